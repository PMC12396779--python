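import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom, norm

from medconf import (
    McqItem,
    ParsedAnswer,
    UncertaintyScores,
    accuracy_with_ci,
    delong_paired_test,
    fisher_exact_2x2,
    grade,
    mcnemar_paired,
    roc_and_auc,
    threshold_block,
    youden_threshold,
)

from conftest import brute_force_auc

# The 6-point worked set used across threshold tests:
# correct scores {0.99, 0.95, 0.9}, incorrect {0.95, 0.6, 0.5}.
WORKED_SCORES = [0.99, 0.95, 0.9, 0.95, 0.6, 0.5]
WORKED_OUTCOMES = [True, True, True, False, False, False]


def _item(item_id="q1", gold="C"):
    return McqItem(
        item_id=item_id,
        stem="s",
        options={L: L.lower() for L in "ABCD"},
        gold=gold,
    )


class TestGrade:
    def _parsed(self, item_id, letter, status="template", conf=90.0):
        if letter is None:
            return ParsedAnswer(item_id=item_id, parse_status="failed")
        return ParsedAnswer(
            item_id=item_id,
            letter=letter,
            expressed_confidence=conf,
            parse_status=status,
        )

    def test_letter_equality(self):
        items = [_item()]
        scores = {"q1": UncertaintyScores()}
        graded, _ = grade(items, [self._parsed("q1", "C")], scores)
        assert graded[0].correct is True
        graded, _ = grade(items, [self._parsed("q1", "A")], scores)
        assert graded[0].correct is False

    def test_failed_parses_excluded_and_tallied(self):
        items = [_item(f"q{i}") for i in range(10)]
        parsed = [
            self._parsed(f"q{i}", None if i < 2 else "C") for i in range(10)
        ]
        graded, exclusions = grade(items, parsed, {})
        assert len(graded) == 8
        assert exclusions["parse_failed"] == 2


class TestAccuracyWithCi:
    def test_wilson_interval_hand_evaluated(self):
        outcomes = [True] * 89 + [False] * 11
        est, low, high = accuracy_with_ci(outcomes)
        assert est == pytest.approx(0.89)
        assert low == pytest.approx(0.8136, abs=5e-4)
        assert high == pytest.approx(0.9374, abs=5e-4)

    def test_boundaries(self):
        est0, low0, _ = accuracy_with_ci([False] * 10)
        assert (est0, low0) == (0.0, 0.0)
        est1, _, high1 = accuracy_with_ci([True] * 10)
        assert est1 == 1.0
        assert high1 == pytest.approx(1.0, abs=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            accuracy_with_ci([])


class TestFisherExact:
    def test_symmetric_table(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_perfect_separation(self):
        assert fisher_exact_2x2(10, 0, 0, 10) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-9
        )

    def test_against_hypergeometric_enumeration(self):
        # Brute-force oracle: sum hypergeometric probabilities of tables
        # (with the same margins) no more likely than the observed one.
        a, b, c, d = 1, 9, 9, 1
        n, row1, col1 = a + b + c + d, a + b, a + c
        p_obs = hypergeom.pmf(a, n, row1, col1)
        p_total = sum(
            hypergeom.pmf(k, n, row1, col1)
            for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
            if hypergeom.pmf(k, n, row1, col1) <= p_obs * (1 + 1e-9)
        )
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(p_total, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestRocAndAuc:
    def test_perfect_separation(self):
        roc = roc_and_auc([0.9, 0.8, 0.1], [True, True, False])
        assert roc.auc == 1.0

    def test_all_ties(self):
        roc = roc_and_auc([0.5] * 6, [True, True, True, False, False, False])
        assert roc.auc == 0.5

    def test_pairwise_hand_count(self):
        roc = roc_and_auc([0.9, 0.4, 0.6, 0.4], [True, True, False, False])
        assert roc.auc == pytest.approx((1 + 1 + 0 + 0.5) / 4)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="AUROC undefined"):
            roc_and_auc([0.1, 0.2], [True, True])

    def test_curve_monotone_and_ci_contains_auc(self, default_graded):
        graded, _ = default_graded
        roc = roc_and_auc(graded["token_prob"], graded["correct"])
        tprs = [tpr for _, tpr, _ in roc.curve]
        fprs = [fpr for _, _, fpr in roc.curve]
        assert tprs == sorted(tprs)
        assert fprs == sorted(fprs)
        assert roc.auc_ci[0] <= roc.auc <= roc.auc_ci[1]
        assert roc.n_pos + roc.n_neg == len(graded)

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n = data.draw(st.integers(min_value=4, max_value=60))
        # few distinct values -> heavy ties
        scores = data.draw(
            st.lists(
                st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                min_size=n,
                max_size=n,
            )
        )
        outcomes = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ys: any(ys) and not all(ys)
            )
        )
        assert roc_and_auc(scores, outcomes).auc == brute_force_auc(
            scores, outcomes
        )

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_invariant_under_monotone_transforms(self, data):
        n = data.draw(st.integers(min_value=4, max_value=40))
        # coarse grid keeps distinct values distinct after the transforms
        scores = np.round(
            np.array(
                data.draw(
                    st.lists(
                        st.floats(min_value=0.01, max_value=0.99),
                        min_size=n,
                        max_size=n,
                    )
                )
            ),
            3,
        )
        scores = np.clip(scores, 0.001, 0.999)
        outcomes = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ys: any(ys) and not all(ys)
            )
        )
        base = roc_and_auc(scores, outcomes).auc
        assert roc_and_auc(np.log(scores), outcomes).auc == pytest.approx(
            base, abs=1e-12
        )
        assert roc_and_auc(3.0 * scores + 2.0, outcomes).auc == pytest.approx(
            base, abs=1e-12
        )

    def test_negation_complements_auc_without_ties(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(np.linspace(0, 1, 40))
        outcomes = rng.random(40) < 0.5
        outcomes[0], outcomes[1] = True, False
        a = roc_and_auc(scores, outcomes).auc
        b = roc_and_auc(-scores, outcomes).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestDelongPairedTest:
    def test_identical_scores_give_p_one(self):
        s = [0.9, 0.8, 0.3, 0.2]
        y = [True, True, False, False]
        auc_a, auc_b, z, p = delong_paired_test(s, s, y)
        assert auc_a == auc_b
        assert p == 1.0

    def test_informative_vs_uninformative_highly_significant(self):
        rng = np.random.default_rng(5)
        n = 200
        y = np.arange(n) < n // 2
        a = y.astype(float) + rng.normal(0, 0.1, n)  # near-perfect separator
        b = rng.normal(0, 1, n)  # pure noise
        *_, p = delong_paired_test(a, b, y)
        assert p < 0.001

    def test_variance_matches_binormal_theory(self):
        # Repeated-draw check: the DeLong SE should approximate the
        # empirical SD of the AUC estimate across replicates.
        rng = np.random.default_rng(7)
        aucs, ses = [], []
        for _ in range(300):
            y = np.concatenate([np.ones(60, bool), np.zeros(60, bool)])
            s = np.where(y, rng.normal(1.0, 1, 120), rng.normal(0, 1, 120))
            roc = roc_and_auc(s, y)
            aucs.append(roc.auc)
            ses.append((roc.auc_ci[1] - roc.auc_ci[0]) / (2 * norm.ppf(0.975)))
        assert np.mean(ses) == pytest.approx(np.std(aucs), rel=0.15)


class TestYoudenThreshold:
    def test_worked_set(self):
        roc = roc_and_auc(WORKED_SCORES, WORKED_OUTCOMES)
        assert youden_threshold(roc) == pytest.approx(0.9)

    def test_all_equal_scores_single_candidate(self):
        roc = roc_and_auc([0.7] * 4, [True, False, True, False])
        assert youden_threshold(roc) == 0.7

    def test_perfect_separation_returns_highest_candidate(self):
        roc = roc_and_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        # J = 1 is reached at t = 0.8 and nowhere higher
        assert youden_threshold(roc) == pytest.approx(0.8)

    def test_exhaustive_sweep_oracle(self):
        rng = np.random.default_rng(21)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=50)
        outcomes = rng.random(50) < 0.5
        outcomes[:2] = [True, False]
        roc = roc_and_auc(scores, outcomes)
        t = youden_threshold(roc)
        pos, neg = scores[outcomes], scores[~outcomes]

        def j(th):
            return np.mean(pos >= th) - np.mean(neg >= th)

        best = max(j(th) for th in np.unique(scores))
        assert j(t) == pytest.approx(best)
        # tie-break: no higher threshold reaches the same J
        higher = [th for th in np.unique(scores) if th > t]
        assert all(j(th) < best - 1e-12 for th in higher)


class TestThresholdBlock:
    def test_worked_set_at_09(self):
        block = threshold_block(WORKED_SCORES, WORKED_OUTCOMES, 0.9)
        assert block.tpr.estimate == pytest.approx(1.0)
        assert block.fpr.estimate == pytest.approx(1 / 3)
        assert block.acc_above.estimate == pytest.approx(3 / 4)
        assert block.acc_below.estimate == pytest.approx(0.0)
        assert block.n_above + block.n_below == 6

    def test_perfect_separator(self):
        block = threshold_block([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.8)
        assert block.acc_above.estimate == 1.0
        assert block.acc_below.estimate == 0.0

    def test_threshold_below_min_flags_empty_stratum(self):
        block = threshold_block([0.5, 0.6, 0.7], [1, 0, 1], 0.0)
        assert block.n_below == 0
        assert "below" in block.empty_strata
        assert block.acc_below.estimate is None
        assert block.acc_above.estimate == pytest.approx(2 / 3)

    def test_strict_variant_excludes_boundary(self):
        block = threshold_block(WORKED_SCORES, WORKED_OUTCOMES, 0.9, strict=True)
        assert block.n_above == 3  # 0.9 itself falls below with '>'


class TestMcnemar:
    def test_symmetric_discordance(self):
        assert mcnemar_paired(5, 5) == pytest.approx(1.0)

    def test_exact_binomial_tail(self):
        assert mcnemar_paired(10, 0) == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_no_discordant_pairs(self):
        assert mcnemar_paired(0, 0) == 1.0

    def test_large_counts_use_chi_square(self):
        # continuity-corrected chi-square: (|b-c|-1)^2/(b+c)
        from scipy.stats import chi2

        b, c = 30, 10
        expected = float(chi2.sf((abs(b - c) - 1) ** 2 / (b + c), 1))
        assert mcnemar_paired(b, c) == pytest.approx(expected, rel=1e-9)
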