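"""Discrimination analysis: does a confidence score separate correct from
incorrect answers?

The positive class is the *correct* answer throughout, so the true
positive rate is the fraction of correct answers scoring at or above a
threshold and the false positive rate is the fraction of incorrect ones
doing so.  AUROC is the Mann-Whitney statistic (ties count 1/2), its CI
and paired comparisons come from DeLong's structural-components method,
and the operating threshold is the Youden-J maximizer over the observed
score values (ties broken toward the highest threshold, the most
conservative flagging rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.proportion import proportion_confint

from .types import GradedAnswer, McqItem, ParsedAnswer, UncertaintyScores

__all__ = [
    "RocAnalysis",
    "ThresholdBlock",
    "grade",
    "accuracy_with_ci",
    "fisher_exact_2x2",
    "roc_and_auc",
    "delong_paired_test",
    "youden_threshold",
    "threshold_block",
    "mcnemar_paired",
]


@dataclass(frozen=True)
class RocAnalysis:
    """ROC curve and AUROC with a DeLong 95%-style CI."""

    curve: list[tuple[float, float, float]]  # (threshold, TPR, FPR)
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class EstimateWithCi:
    estimate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]


@dataclass(frozen=True)
class ThresholdBlock:
    """Operating characteristics at one threshold (score >= t is 'above')."""

    threshold: float
    tpr: EstimateWithCi
    fpr: EstimateWithCi
    acc_above: EstimateWithCi
    acc_below: EstimateWithCi
    n_above: int
    n_below: int
    empty_strata: tuple[str, ...] = ()


def grade(
    items: Sequence[McqItem],
    parsed: Sequence[ParsedAnswer],
    scores: Mapping[str, UncertaintyScores],
) -> tuple[list[GradedAnswer], dict[str, int]]:
    """Join items, parsed answers and scores into graded answers.

    Correctness is exact letter equality with the gold letter.  Failed
    parses are excluded and tallied; a parsed letter outside the item's
    option set is counted incorrect (with a tally).  Returns
    ``(graded, exclusions)`` where exclusions counts ``parse_failed``,
    ``unknown_item`` and ``letter_not_in_options``.
    """
    by_id = {item.item_id: item for item in items}
    graded: list[GradedAnswer] = []
    exclusions = {"parse_failed": 0, "unknown_item": 0, "letter_not_in_options": 0}
    for pa in parsed:
        if pa.parse_status == "failed" or pa.letter is None:
            exclusions["parse_failed"] += 1
            continue
        item = by_id.get(pa.item_id)
        if item is None:
            exclusions["unknown_item"] += 1
            continue
        if pa.letter not in item.options:
            exclusions["letter_not_in_options"] += 1
        graded.append(
            GradedAnswer(
                item_id=pa.item_id,
                correct=(pa.letter == item.gold),
                scores=scores.get(pa.item_id, UncertaintyScores()),
                letter=pa.letter,
                gold=item.gold,
                parse_status=pa.parse_status,
                expressed_confidence=pa.expressed_confidence,
            )
        )
    return graded, exclusions


def accuracy_with_ci(
    graded: Sequence[GradedAnswer] | Sequence[bool], ci_level: float = 0.95
) -> tuple[float, float, float]:
    """Mean correctness with a Wilson score interval."""
    outcomes = [
        g.correct if isinstance(g, GradedAnswer) else bool(g) for g in graded
    ]
    n = len(outcomes)
    if n == 0:
        raise ValueError("accuracy undefined on empty input")
    k = sum(outcomes)
    low, high = proportion_confint(k, n, alpha=1 - ci_level, method="wilson")
    return k / n, float(low), float(high)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]]."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("all margins are zero")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(
    scores: np.ndarray, outcomes: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components (V10 per positive, V01 per negative)."""
    pos = scores[outcomes]
    neg = scores[~outcomes]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    v10 = (tz[:m] - tx) / n  # one component per correct answer
    v01 = 1.0 - (tz[m:] - ty) / m  # one per incorrect answer
    # Sums of midranks are exact half-integers, so this equals the
    # pairwise count (wins + ties/2) / (m*n) to the last bit.
    auc = float((tz[:m].sum() - m * (m + 1) / 2) / (m * n))
    return auc, v10, v01


def roc_and_auc(
    scores: Iterable[float], outcomes: Iterable[bool], ci_level: float = 0.95
) -> RocAnalysis:
    """ROC curve, Mann-Whitney AUROC and DeLong normal-approximation CI.

    Candidate thresholds are the observed score values (descending); at
    each, TPR/FPR use the ``score >= threshold`` convention.
    """
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(outcomes), dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    auc, v10, v01 = _delong_components(s, y)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(0.5 + ci_level / 2)
    half = z * math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    thresholds = np.unique(s)[::-1]
    pos = s[y]
    neg = s[~y]
    curve = [
        (float(t), float(np.mean(pos >= t)), float(np.mean(neg >= t)))
        for t in thresholds
    ]
    return RocAnalysis(curve=curve, auc=auc, auc_ci=ci, n_pos=m, n_neg=n)


def delong_paired_test(
    scores_a: Iterable[float],
    scores_b: Iterable[float],
    outcomes: Iterable[bool],
) -> tuple[float, float, float, float]:
    """DeLong test for two correlated AUROCs on the same items.

    Returns ``(auc_a, auc_b, z, p_two_sided)``.  Zero variance of the
    difference with equal AUCs yields p = 1; zero variance with unequal
    AUCs is an error (degenerate inputs).
    """
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    y = np.asarray(list(outcomes), dtype=bool)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("paired score sets must align with outcomes")
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    m, n = len(v10_a), len(v01_a)
    # 2x2 covariance of (auc_a, auc_b) from the structural components.
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        if math.isclose(auc_a, auc_b, abs_tol=1e-12):
            return auc_a, auc_b, 0.0, 1.0
        raise ValueError(
            "DeLong variance of the AUC difference is zero but the AUCs differ"
        )
    z = diff / math.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


def youden_threshold(roc: RocAnalysis) -> float:
    """Threshold maximizing J = TPR - FPR; ties go to the highest threshold.

    The curve is stored threshold-descending, so the first maximizer is
    the highest one (the most conservative rule: fewest answers flagged
    as confident).
    """
    if not roc.curve:
        raise ValueError("empty ROC curve")
    best_t, best_j = roc.curve[0][0], -math.inf
    for t, tpr, fpr in roc.curve:
        j = tpr - fpr
        if j > best_j:
            best_t, best_j = t, j
    return best_t


def _wilson(k: int, n: int, ci_level: float) -> EstimateWithCi:
    if n == 0:
        return EstimateWithCi(None, None, None)
    low, high = proportion_confint(k, n, alpha=1 - ci_level, method="wilson")
    return EstimateWithCi(k / n, float(low), float(high))


def threshold_block(
    scores: Iterable[float],
    outcomes: Iterable[bool],
    threshold: float,
    ci_level: float = 0.95,
    strict: bool = False,
) -> ThresholdBlock:
    """TPR/FPR and above/below-threshold accuracy with Wilson CIs.

    'Above' means ``score >= threshold`` (``>`` with ``strict=True``).
    Empty strata are flagged rather than raising.
    """
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(outcomes), dtype=bool)
    above = s > threshold if strict else s >= threshold
    n_above = int(above.sum())
    n_below = int(len(s) - n_above)
    empty = []
    if y.sum() == 0:
        empty.append("correct")
    if (~y).sum() == 0:
        empty.append("incorrect")
    if n_above == 0:
        empty.append("above")
    if n_below == 0:
        empty.append("below")
    return ThresholdBlock(
        threshold=float(threshold),
        tpr=_wilson(int((above & y).sum()), int(y.sum()), ci_level),
        fpr=_wilson(int((above & ~y).sum()), int((~y).sum()), ci_level),
        acc_above=_wilson(int((above & y).sum()), n_above, ci_level),
        acc_below=_wilson(int((~above & y).sum()), n_below, ci_level),
        n_above=n_above,
        n_below=n_below,
        empty_strata=tuple(empty),
    )


def mcnemar_paired(b: int, c: int) -> float:
    """Two-sided McNemar p-value from the discordant-pair counts.

    Exact binomial when b + c < 25, chi-square with continuity correction
    otherwise; b + c = 0 gives p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        return 1.0
    table = [[0, b], [c, 0]]
    exact = (b + c) < 25
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(min(res.pvalue, 1.0))
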