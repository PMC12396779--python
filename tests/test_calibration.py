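import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medconf import (
    ace,
    adaptive_bins,
    bootstrap_ci,
    bootstrap_paired_pvalue,
    brier,
    calibration_curve,
)

# Hand-computed 6-record / 2-bin toy:
# bin1 conf (0.6, 0.7, 0.8) outcomes (1, 0, 1); bin2 conf (0.9, 0.95, 1.0)
# outcomes (1, 1, 0) -> ACE = (|2/3 - 0.7| + |2/3 - 0.95|) / 2
TOY_CONF = [0.6, 0.7, 0.8, 0.9, 0.95, 1.0]
TOY_OUTCOMES = [1, 0, 1, 1, 1, 0]
TOY_ACE = (abs(2 / 3 - 0.7) + abs(2 / 3 - 0.95)) / 2


class TestAdaptiveBins:
    def test_even_split(self):
        bins = adaptive_bins(np.linspace(0, 1, 10), [1] * 10, 5)
        assert [b.n for b in bins] == [2, 2, 2, 2, 2]

    def test_remainder_goes_to_earliest_bins(self):
        bins = adaptive_bins(np.linspace(0, 1, 7), [1] * 7, 3)
        assert [b.n for b in bins] == [3, 2, 2]

    def test_bins_partition_and_are_ordered(self):
        rng = np.random.default_rng(1)
        conf = rng.random(53)
        out = rng.random(53) < conf
        bins = adaptive_bins(conf, out, 7)
        assert sum(b.n for b in bins) == 53
        assert max(b.n for b in bins) - min(b.n for b in bins) <= 1
        for b in bins:
            assert b.conf_range[0] <= b.conf_mean <= b.conf_range[1]
        tops = [b.conf_range[1] for b in bins]
        assert tops == sorted(tops)

    def test_all_equal_confidences_span_bins(self):
        bins = adaptive_bins([0.8] * 4, [1, 1, 0, 0], 2)
        assert all(b.conf_mean == 0.8 for b in bins)
        # stable sort keeps input order, so outcomes split (1,1) / (0,0)
        assert [b.acc for b in bins] == [1.0, 0.0]

    def test_too_many_bins_raises(self):
        with pytest.raises(ValueError, match="n_bins"):
            adaptive_bins([0.5, 0.6], [1, 0], 3)


class TestAce:
    def test_degenerate_perfectly_calibrated(self):
        assert ace([1.0] * 8, [True] * 8, 2) == 0.0

    def test_constant_offset(self):
        conf = [1.0] * 10
        outcomes = [True] * 6 + [False] * 4
        for n_bins in (1, 2, 5):
            assert ace(conf, outcomes, n_bins) == pytest.approx(0.4)

    def test_hand_computed_toy(self):
        assert ace(TOY_CONF, TOY_OUTCOMES, 2) == pytest.approx(TOY_ACE, abs=1e-12)
        assert TOY_ACE == pytest.approx(0.15833, abs=5e-6)

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_single_bin_equals_overall_gap(self, data):
        n = data.draw(st.integers(min_value=1, max_value=50))
        conf = data.draw(
            st.lists(
                st.floats(min_value=0.0, max_value=1.0), min_size=n, max_size=n
            )
        )
        outcomes = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        expected = abs(np.mean(outcomes) - np.mean(conf))
        assert ace(conf, outcomes, 1) == pytest.approx(expected, abs=1e-12)

    def test_zero_when_every_bin_matches(self):
        # two bins, each internally calibrated
        conf = [0.25] * 4 + [0.75] * 4
        outcomes = [1, 0, 0, 0, 1, 1, 1, 0]
        assert ace(conf, outcomes, 2) == pytest.approx(0.0)


class TestBrier:
    def test_perfect_forecast(self):
        assert brier([1.0], [True]) == 0.0

    def test_single_miss(self):
        assert brier([0.7], [False]) == pytest.approx(0.49)

    def test_constant_forecast_matches_analytic_variance(self):
        rng = np.random.default_rng(123)
        p = 0.7
        outcomes = rng.random(10000) < p
        assert brier([p] * 10000, outcomes) == pytest.approx(
            p * (1 - p), abs=0.01
        )

    def test_minimized_at_base_rate_among_constants(self):
        rng = np.random.default_rng(9)
        outcomes = rng.random(500) < 0.63
        base = outcomes.mean()
        grid = np.linspace(0, 1, 201)
        scores = [brier([c] * 500, outcomes) for c in grid]
        best = grid[int(np.argmin(scores))]
        assert abs(best - base) <= 0.005 + 1e-12

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            brier([], [])


class TestBootstrapCi:
    def test_degenerate_all_ones(self):
        stat = lambda c, o: float(np.mean(c))
        assert bootstrap_ci(stat, [1.0] * 20, [True] * 20, reps=200, seed=0) == (
            1.0,
            1.0,
        )

    def test_deterministic_given_seed(self):
        stat = lambda c, o: ace(c, o, 2)
        a = bootstrap_ci(stat, TOY_CONF, TOY_OUTCOMES, reps=1000, seed=42)
        b = bootstrap_ci(stat, TOY_CONF, TOY_OUTCOMES, reps=1000, seed=42)
        assert a == b
        c = bootstrap_ci(stat, TOY_CONF, TOY_OUTCOMES, reps=1000, seed=43)
        assert a != c

    def test_coverage_for_brier(self):
        # 95% interval should cover the true Brier value in >= 90% of
        # simulated datasets (percentile bootstrap is approximate).
        rng = np.random.default_rng(77)
        p = 0.7
        true_brier = p * (1 - p)
        covered = 0
        n_datasets = 200
        for i in range(n_datasets):
            outcomes = rng.random(200) < p
            conf = np.full(200, p)
            low, high = bootstrap_ci(
                brier, conf, outcomes, reps=200, seed=1000 + i
            )
            covered += low <= true_brier <= high
        assert covered / n_datasets >= 0.90

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(brier, TOY_CONF, TOY_OUTCOMES, reps=50, seed=0)


class TestBootstrapPairedPvalue:
    def test_identical_metrics_give_p_one(self):
        p = bootstrap_paired_pvalue(
            brier, TOY_CONF, TOY_CONF, TOY_OUTCOMES, reps=499, seed=0
        )
        assert p == 1.0

    def test_large_miscalibration_detected(self):
        rng = np.random.default_rng(3)
        true_p = rng.uniform(0.2, 0.9, 1000)
        outcomes = rng.random(1000) < true_p
        conf_good = true_p
        conf_bad = np.clip(true_p + 0.3, 0, 1)
        p = bootstrap_paired_pvalue(
            brier, conf_good, conf_bad, outcomes, reps=999, seed=4
        )
        assert p <= 0.01

    def test_smoothing_floor(self):
        rng = np.random.default_rng(3)
        true_p = rng.uniform(0.2, 0.9, 500)
        outcomes = rng.random(500) < true_p
        p = bootstrap_paired_pvalue(
            brier,
            true_p,
            np.clip(true_p + 0.4, 0, 1),
            outcomes,
            reps=999,
            seed=5,
        )
        assert p == pytest.approx(2 / 1000)


class TestCalibrationCurve:
    def test_single_bin_point(self):
        bins = adaptive_bins(TOY_CONF, TOY_OUTCOMES, 1)
        points = calibration_curve(bins)
        assert len(points) == 1
        conf_mean, acc, n = points[0]
        assert conf_mean == pytest.approx(np.mean(TOY_CONF))
        assert acc == pytest.approx(np.mean(TOY_OUTCOMES))
        assert n == 6

    def test_calibrated_simulation_hugs_identity(self):
        rng = np.random.default_rng(11)
        conf = rng.uniform(0.05, 0.95, 20000)
        outcomes = rng.random(20000) < conf
        bins = adaptive_bins(conf, outcomes, 10)
        gap = max(abs(a - c) for c, a, _ in calibration_curve(bins))
        assert gap <= 0.03

    def test_overconfident_simulation_sits_below_identity(self):
        rng = np.random.default_rng(12)
        true_p = rng.uniform(0.1, 0.8, 5000)
        outcomes = rng.random(5000) < true_p
        conf = np.clip(true_p + 0.15, 0, 1)
        bins = adaptive_bins(conf, outcomes, 10)
        assert all(acc < conf_mean for conf_mean, acc, _ in calibration_curve(bins))
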