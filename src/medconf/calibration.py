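"""Calibration analysis: does stated confidence match empirical accuracy?

Calibration is quantified with the adaptive calibration error (ACE) —
the mean absolute gap between accuracy and mean confidence across
equal-mass confidence bins, which is robust to the heavily skewed
confidence distributions these models produce — and the Brier score.
Interval estimates use the seeded percentile bootstrap; paired metric
comparisons use a bootstrapped two-sided p-value.  An ACE above 0.25 is
flagged as poor calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "CalibrationBin",
    "adaptive_bins",
    "ace",
    "brier",
    "bootstrap_ci",
    "bootstrap_paired_pvalue",
    "calibration_curve",
    "ACE_POOR_CALIBRATION",
]

ACE_POOR_CALIBRATION = 0.25


@dataclass(frozen=True)
class CalibrationBin:
    """One equal-mass confidence bin."""

    index: int
    conf_mean: float
    acc: float
    n: int
    conf_range: tuple[float, float]


def _as_arrays(
    confidences: Iterable[float], outcomes: Iterable[bool]
) -> tuple[np.ndarray, np.ndarray]:
    conf = np.asarray(list(confidences), dtype=float)
    y = np.asarray(list(outcomes), dtype=bool)
    if conf.shape != y.shape:
        raise ValueError("confidences and outcomes must have equal length")
    if conf.size and (conf.min() < 0 or conf.max() > 1):
        raise ValueError("confidences must be normalized to [0, 1]")
    return conf, y


def adaptive_bins(
    confidences: Iterable[float],
    outcomes: Iterable[bool],
    n_bins: int,
) -> list[CalibrationBin]:
    """Partition the sample into contiguous equal-mass confidence bins.

    Samples are sorted by confidence ascending (stable, so ties keep
    input order and may span bins) and split into ``n_bins`` groups whose
    sizes differ by at most one, larger bins first.
    """
    conf, y = _as_arrays(confidences, outcomes)
    n = conf.size
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n < n_bins:
        raise ValueError(
            f"cannot form {n_bins} bins from {n} samples; use n_bins <= {n}"
        )
    order = np.argsort(conf, kind="stable")
    conf_sorted = conf[order]
    y_sorted = y[order]
    base, rem = divmod(n, n_bins)
    bins: list[CalibrationBin] = []
    start = 0
    for b in range(n_bins):
        size = base + (1 if b < rem else 0)
        stop = start + size
        c = conf_sorted[start:stop]
        o = y_sorted[start:stop]
        bins.append(
            CalibrationBin(
                index=b,
                conf_mean=float(c.mean()),
                acc=float(o.mean()),
                n=size,
                conf_range=(float(c[0]), float(c[-1])),
            )
        )
        start = stop
    return bins


def ace(
    confidences: Iterable[float],
    outcomes: Iterable[bool],
    n_bins: int = 10,
) -> float:
    """Adaptive calibration error: mean |accuracy - mean confidence| per bin."""
    bins = adaptive_bins(confidences, outcomes, n_bins)
    return float(np.mean([abs(b.acc - b.conf_mean) for b in bins]))


def brier(confidences: Iterable[float], outcomes: Iterable[bool]) -> float:
    """Mean squared difference between confidence and binary correctness."""
    conf, y = _as_arrays(confidences, outcomes)
    if conf.size == 0:
        raise ValueError("Brier score undefined on empty input")
    return float(np.mean((conf - y.astype(float)) ** 2))


def _resample_indices(
    rng: np.random.Generator, y: np.ndarray, max_retries: int = 1000
) -> np.ndarray:
    """Resample with replacement; redraw degenerate single-class resamples.

    A resample is only considered degenerate when the original data had
    both outcome classes but the resample does not (all-correct or
    all-incorrect *inputs* are legitimate and pass through unchanged).
    """
    n = y.size
    mixed = bool(y.any()) and bool((~y).any())
    for _ in range(max_retries):
        idx = rng.integers(0, n, size=n)
        if not mixed:
            return idx
        yy = y[idx]
        if yy.any() and (~yy).any():
            return idx
    raise RuntimeError("could not draw a non-degenerate bootstrap resample")


def bootstrap_ci(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    confidences: Iterable[float],
    outcomes: Iterable[bool],
    reps: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, float]:
    """Seeded percentile-bootstrap interval for a calibration statistic."""
    if reps < 200:
        raise ValueError("bootstrap needs reps >= 200")
    conf, y = _as_arrays(confidences, outcomes)
    rng = np.random.default_rng(seed)
    values = np.empty(reps)
    for r in range(reps):
        idx = _resample_indices(rng, y)
        values[r] = statistic(conf[idx], y[idx])
    alpha = 1 - ci_level
    low, high = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return float(low), float(high)


def bootstrap_paired_pvalue(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    confidences_a: Iterable[float],
    confidences_b: Iterable[float],
    outcomes: Iterable[bool],
    reps: int = 2000,
    seed: int = 0,
) -> float:
    """Bootstrapped two-sided p for stat(A) - stat(B) on paired data.

    Items are resampled jointly; with r_le = #{diff* <= 0} and
    r_ge = #{diff* >= 0}, p = 2 * min((r_le+1), (r_ge+1)) / (reps+1),
    capped at 1 (add-one smoothing, so the smallest attainable p is
    2/(reps+1)).
    """
    if reps < 200:
        raise ValueError("bootstrap needs reps >= 200")
    conf_a, y = _as_arrays(confidences_a, outcomes)
    conf_b, y2 = _as_arrays(confidences_b, outcomes)
    if conf_a.shape != conf_b.shape:
        raise ValueError("paired confidence vectors must have equal length")
    rng = np.random.default_rng(seed)
    diffs = np.empty(reps)
    for r in range(reps):
        idx = _resample_indices(rng, y)
        diffs[r] = statistic(conf_a[idx], y[idx]) - statistic(conf_b[idx], y[idx])
    r_le = int((diffs <= 0).sum())
    r_ge = int((diffs >= 0).sum())
    p = 2 * min(r_le + 1, r_ge + 1) / (reps + 1)
    return float(min(p, 1.0))


def calibration_curve(
    bins: Sequence[CalibrationBin],
) -> list[tuple[float, float, int]]:
    """(mean confidence, accuracy, n) points sorted by confidence.

    Plot-ready against the identity line: points below it indicate
    overconfidence.
    """
    return sorted(((b.conf_mean, b.acc, b.n) for b in bins), key=lambda p: p[0])
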