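"""End-to-end evaluation: parse -> score -> discriminate -> calibrate -> report.

``run_evaluation`` consumes a dataset plus a model answer log and
produces, per confidence signal, a discrimination report (AUROC with
DeLong CI, Youden threshold, TPR/FPR and above/below-threshold accuracy,
DeLong and McNemar comparisons against expressed confidence) and — for
the two signals that are probabilities — a calibration report (ACE and
Brier with percentile-bootstrap CIs and a bootstrapped paired p-value).
Everything is seeded and deterministic: identical inputs, config and
seed give byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .calibration import (
    ACE_POOR_CALIBRATION,
    CalibrationBin,
    ace,
    adaptive_bins,
    bootstrap_ci,
    bootstrap_paired_pvalue,
    brier,
    calibration_curve,
)
from .discrimination import (
    RocAnalysis,
    ThresholdBlock,
    accuracy_with_ci,
    delong_paired_test,
    mcnemar_paired,
    roc_and_auc,
    threshold_block,
    youden_threshold,
)
from .io import read_mcq_dataset, read_response_log, write_report_tables
from .metrics import score_answer
from .parsing import AnswerTokenNotFoundError, locate_answer_token, parse_response
from .types import McqItem, ResponseRecord

logger = logging.getLogger(__name__)

#: Signals usable for discrimination, with their confidence orientation.
#: Entropy and perplexity measure doubt, so they enter ROC analyses negated.
METRIC_ORIENTATION = {
    "expressed": 1.0,
    "token_prob": 1.0,
    "entropy": -1.0,
    "perplexity": -1.0,
}

#: Column of the graded-answers frame holding each signal's raw values.
_METRIC_COLUMN = {
    "expressed": "expressed_conf",
    "token_prob": "token_prob",
    "entropy": "entropy_bits",
    "perplexity": "perplexity",
}

#: Signals that are probabilities, hence eligible for calibration analysis.
CALIBRATABLE = ("expressed", "token_prob")


class RunConfig(BaseModel):
    """One evaluation run: inputs, metric selection, and analysis settings."""

    dataset_path: str
    response_log_path: str
    output_dir: str
    metrics: list[str] = Field(
        default_factory=lambda: ["expressed", "token_prob", "entropy", "perplexity"]
    )
    n_bins: int = Field(default=10, ge=1)
    bootstrap_reps: int = Field(default=2000, ge=0)
    seed: Optional[int] = None
    ci_level: float = Field(default=0.95, gt=0.0, lt=1.0)
    confidence_scale_max: int = 100
    label: str = ""

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not self.metrics:
            raise ValueError("metrics must be non-empty")
        unknown = set(self.metrics) - set(METRIC_ORIENTATION)
        if unknown:
            raise ValueError(f"unknown metrics {sorted(unknown)}")
        if self.confidence_scale_max not in (100, 1):
            raise ValueError("confidence_scale_max must be 100 or 1")
        if self.bootstrap_reps > 0 and self.seed is None:
            raise ValueError("seed is mandatory when bootstrap_reps > 0")
        return self


@dataclass
class AccuracyReport:
    model_tag: str
    n: int
    accuracy: float
    ci_low: float
    ci_high: float
    exclusions: dict[str, int]

    report_kind = "accuracy"

    def report_rows(self) -> list[dict]:
        return [
            {
                "model_tag": self.model_tag,
                "n": self.n,
                "accuracy": self.accuracy,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                **{f"excluded_{k}": v for k, v in sorted(self.exclusions.items())},
            }
        ]


@dataclass
class DiscriminationReport:
    """Table-1-shaped block for one confidence signal."""

    model_tag: str
    metric: str
    roc: RocAnalysis
    optimal_threshold: float
    block: ThresholdBlock
    delong_p_vs_expressed: Optional[float] = None
    mcnemar_tpr_p_vs_expressed: Optional[float] = None
    mcnemar_fpr_p_vs_expressed: Optional[float] = None

    report_kind = "discrimination"

    def report_rows(self) -> list[dict]:
        b = self.block
        return [
            {
                "model_tag": self.model_tag,
                "metric": self.metric,
                "auroc": self.roc.auc,
                "auroc_ci_low": self.roc.auc_ci[0],
                "auroc_ci_high": self.roc.auc_ci[1],
                "n_pos": self.roc.n_pos,
                "n_neg": self.roc.n_neg,
                "optimal_threshold": self.optimal_threshold,
                "tpr": b.tpr.estimate,
                "tpr_ci_low": b.tpr.ci_low,
                "tpr_ci_high": b.tpr.ci_high,
                "fpr": b.fpr.estimate,
                "fpr_ci_low": b.fpr.ci_low,
                "fpr_ci_high": b.fpr.ci_high,
                "acc_above": b.acc_above.estimate,
                "acc_above_ci_low": b.acc_above.ci_low,
                "acc_above_ci_high": b.acc_above.ci_high,
                "acc_below": b.acc_below.estimate,
                "acc_below_ci_low": b.acc_below.ci_low,
                "acc_below_ci_high": b.acc_below.ci_high,
                "n_above": b.n_above,
                "n_below": b.n_below,
                "p_vs_expressed": self.delong_p_vs_expressed,
                "mcnemar_tpr_p": self.mcnemar_tpr_p_vs_expressed,
                "mcnemar_fpr_p": self.mcnemar_fpr_p_vs_expressed,
            }
        ]


@dataclass
class CalibrationReport:
    model_tag: str
    metric: str
    ace: float
    ace_ci: tuple[Optional[float], Optional[float]]
    brier: float
    brier_ci: tuple[Optional[float], Optional[float]]
    bins: list[CalibrationBin]
    n_bins: int
    flag_poor: bool
    ace_p_vs_expressed: Optional[float] = None
    brier_p_vs_expressed: Optional[float] = None

    report_kind = "calibration"

    def report_rows(self) -> list[dict]:
        return [
            {
                "model_tag": self.model_tag,
                "metric": self.metric,
                "ace": self.ace,
                "ace_ci_low": self.ace_ci[0],
                "ace_ci_high": self.ace_ci[1],
                "brier": self.brier,
                "brier_ci_low": self.brier_ci[0],
                "brier_ci_high": self.brier_ci[1],
                "n_bins": self.n_bins,
                "flag_poor": self.flag_poor,
                "ace_p_vs_expressed": self.ace_p_vs_expressed,
                "brier_p_vs_expressed": self.brier_p_vs_expressed,
            }
        ]


@dataclass
class CalibrationCurveReport:
    model_tag: str
    metric: str
    points: list[tuple[float, float, int]]

    report_kind = "calibration_curve"

    def report_rows(self) -> list[dict]:
        return [
            {
                "model_tag": self.model_tag,
                "metric": self.metric,
                "conf_mean": c,
                "acc": a,
                "n": n,
            }
            for c, a, n in self.points
        ]


@dataclass
class EvaluationResult:
    graded: pd.DataFrame
    accuracy: AccuracyReport
    discrimination: dict[str, DiscriminationReport]
    calibration: dict[str, CalibrationReport]
    exclusions: dict[str, int]
    manifest: dict = field(default_factory=dict)

    @property
    def reports(self) -> list:
        out: list = [self.accuracy]
        out.extend(self.discrimination.values())
        for metric, rep in self.calibration.items():
            out.append(rep)
            out.append(
                CalibrationCurveReport(
                    rep.model_tag, metric, calibration_curve(rep.bins)
                )
            )
        return out


def grade_log(
    items: list[McqItem],
    records: list[ResponseRecord],
    confidence_scale_max: int = 100,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Parse and score an answer log against its dataset.

    Only the first record per (item_id, model_tag, prompt_variant) is
    graded.  Scores are computed from the response record alone — gold
    letters enter only the final correctness column.  Returns the graded
    frame plus an exclusion tally (failed parses, answer token not found,
    missing expressed confidence).
    """
    by_id = {item.item_id: item for item in items}
    exclusions = {
        "parse_failed": 0,
        "answer_token_not_found": 0,
        "no_expressed_confidence": 0,
        "unknown_item": 0,
    }
    rows = []
    seen: set[tuple[str, str, str]] = set()
    for rec in records:
        key = (rec.item_id, rec.model_tag, rec.prompt_variant)
        if key in seen:
            continue
        seen.add(key)
        item = by_id.get(rec.item_id)
        if item is None:
            exclusions["unknown_item"] += 1
            continue
        parsed = parse_response(rec.raw_text, confidence_scale_max)
        parsed = parsed.model_copy(update={"item_id": rec.item_id})
        if parsed.parse_status == "failed" or parsed.letter is None:
            exclusions["parse_failed"] += 1
            continue
        if parsed.expressed_confidence is None:
            exclusions["no_expressed_confidence"] += 1
        try:
            idx = locate_answer_token(rec, parsed.letter)
            scores = score_answer(rec, parsed, item.letters, idx)
        except AnswerTokenNotFoundError:
            exclusions["answer_token_not_found"] += 1
            scores = None
        rows.append(
            {
                "item_id": rec.item_id,
                "model_tag": rec.model_tag,
                "prompt_variant": rec.prompt_variant,
                "letter": parsed.letter,
                "gold": item.gold,
                "correct": parsed.letter == item.gold,
                "parse_status": parsed.parse_status,
                "expressed_conf": (
                    None
                    if parsed.expressed_confidence is None
                    else parsed.expressed_confidence
                ),
                "expressed_conf_norm": (
                    None
                    if parsed.expressed_confidence is None
                    else parsed.expressed_confidence / parsed.confidence_scale_max
                ),
                "token_prob": None if scores is None else scores.token_prob,
                "entropy_bits": None if scores is None else scores.entropy_bits,
                "perplexity": None if scores is None else scores.perplexity,
            }
        )
    columns = [
        "item_id", "model_tag", "prompt_variant", "letter", "gold", "correct",
        "parse_status", "expressed_conf", "expressed_conf_norm", "token_prob",
        "entropy_bits", "perplexity",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    return frame, exclusions


def _metric_frame(graded: pd.DataFrame, metric: str) -> pd.DataFrame:
    col = _METRIC_COLUMN[metric]
    sub = graded[graded[col].notna()][["item_id", "correct", col]].copy()
    sub["score"] = sub[col].astype(float) * METRIC_ORIENTATION[metric]
    sub["raw"] = sub[col].astype(float)
    return sub


def _discriminate(
    graded: pd.DataFrame,
    metric: str,
    model_tag: str,
    ci_level: float,
) -> tuple[DiscriminationReport, pd.DataFrame]:
    sub = _metric_frame(graded, metric)
    if sub.empty:
        raise ValueError(f"metric {metric!r} absent from the answer log")
    roc = roc_and_auc(sub["score"], sub["correct"], ci_level)
    t = youden_threshold(roc)
    block = threshold_block(sub["score"], sub["correct"], t, ci_level)
    # Report the threshold on the signal's native scale.
    native_t = t * METRIC_ORIENTATION[metric]
    report = DiscriminationReport(
        model_tag=model_tag,
        metric=metric,
        roc=roc,
        optimal_threshold=native_t,
        block=block,
    )
    return report, sub


def run_evaluation(config: RunConfig) -> EvaluationResult:
    """Execute the full analysis sequence and write CSV reports.

    Raises when the log is empty, when a requested metric has no values,
    or when only one correctness class is present (AUROC undefined).
    """
    items = read_mcq_dataset(config.dataset_path)
    records = read_response_log(config.response_log_path)
    if not records:
        raise ValueError(f"empty response log: {config.response_log_path}")
    graded, exclusions = grade_log(items, records, config.confidence_scale_max)
    if graded.empty:
        raise ValueError("no gradable answers after parsing")
    model_tag = graded["model_tag"].iloc[0] or config.label or "model"

    n_correct = int(graded["correct"].sum())
    if n_correct == 0 or n_correct == len(graded):
        raise ValueError(
            "both correct and incorrect answers are required for "
            "discrimination analysis"
        )

    est, lo, hi = accuracy_with_ci(list(graded["correct"]), config.ci_level)
    acc_report = AccuracyReport(
        model_tag=model_tag,
        n=len(graded),
        accuracy=est,
        ci_low=lo,
        ci_high=hi,
        exclusions=exclusions,
    )

    discrimination: dict[str, DiscriminationReport] = {}
    frames: dict[str, pd.DataFrame] = {}
    for metric in config.metrics:
        discrimination[metric], frames[metric] = _discriminate(
            graded, metric, model_tag, config.ci_level
        )

    # Paired comparisons against expressed confidence on common items.
    if "expressed" in discrimination:
        expr = frames["expressed"].set_index("item_id")
        t_expr = discrimination["expressed"].block.threshold
        for metric in config.metrics:
            if metric == "expressed":
                continue
            other = frames[metric].set_index("item_id")
            common = expr.index.intersection(other.index)
            if len(common) == 0:
                continue
            e = expr.loc[common]
            o = other.loc[common]
            y = o["correct"].to_numpy(dtype=bool)
            _, _, _, p = delong_paired_test(
                o["score"].to_numpy(), e["score"].to_numpy(), y
            )
            rep = discrimination[metric]
            rep.delong_p_vs_expressed = p
            above_o = o["score"].to_numpy() >= discrimination[metric].block.threshold
            above_e = e["score"].to_numpy() >= t_expr
            for label, mask in (("tpr", y), ("fpr", ~y)):
                b = int((above_o & ~above_e & mask).sum())
                c = int((~above_o & above_e & mask).sum())
                p_mc = mcnemar_paired(b, c)
                if label == "tpr":
                    rep.mcnemar_tpr_p_vs_expressed = p_mc
                else:
                    rep.mcnemar_fpr_p_vs_expressed = p_mc

    calibration: dict[str, CalibrationReport] = {}
    cal_metrics = [m for m in config.metrics if m in CALIBRATABLE]
    for metric in cal_metrics:
        col = "expressed_conf_norm" if metric == "expressed" else "token_prob"
        sub = graded[graded[col].notna()]
        conf = sub[col].to_numpy(dtype=float)
        y = sub["correct"].to_numpy(dtype=bool)
        ace_val = ace(conf, y, config.n_bins)
        brier_val = brier(conf, y)
        if config.bootstrap_reps > 0:
            assert config.seed is not None
            ace_ci = bootstrap_ci(
                lambda c, o: ace(c, o, config.n_bins),
                conf, y,
                reps=config.bootstrap_reps,
                seed=config.seed,
                ci_level=config.ci_level,
            )
            brier_ci = bootstrap_ci(
                brier, conf, y,
                reps=config.bootstrap_reps,
                seed=config.seed + 1,
                ci_level=config.ci_level,
            )
        else:
            ace_ci = (None, None)
            brier_ci = (None, None)
        calibration[metric] = CalibrationReport(
            model_tag=model_tag,
            metric=metric,
            ace=ace_val,
            ace_ci=ace_ci,
            brier=brier_val,
            brier_ci=brier_ci,
            bins=adaptive_bins(conf, y, config.n_bins),
            n_bins=config.n_bins,
            flag_poor=ace_val > ACE_POOR_CALIBRATION,
        )

    if (
        "expressed" in calibration
        and "token_prob" in calibration
        and config.bootstrap_reps > 0
    ):
        both = graded[
            graded["expressed_conf_norm"].notna() & graded["token_prob"].notna()
        ]
        conf_t = both["token_prob"].to_numpy(dtype=float)
        conf_e = both["expressed_conf_norm"].to_numpy(dtype=float)
        y = both["correct"].to_numpy(dtype=bool)
        assert config.seed is not None
        calibration["token_prob"].ace_p_vs_expressed = bootstrap_paired_pvalue(
            lambda c, o: ace(c, o, config.n_bins),
            conf_t, conf_e, y,
            reps=config.bootstrap_reps, seed=config.seed + 2,
        )
        calibration["token_prob"].brier_p_vs_expressed = bootstrap_paired_pvalue(
            brier, conf_t, conf_e, y,
            reps=config.bootstrap_reps, seed=config.seed + 3,
        )

    manifest = {
        "medconf_version": __version__,
        "config": config.model_dump(),
    }
    result = EvaluationResult(
        graded=graded,
        accuracy=acc_report,
        discrimination=discrimination,
        calibration=calibration,
        exclusions=exclusions,
        manifest=manifest,
    )

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_report_tables(result.reports, out_dir)
    _write_scores_csv(graded, out_dir / "scores.csv")
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result


def _write_scores_csv(graded: pd.DataFrame, path: Path) -> None:
    cols = [
        "item_id", "letter", "correct", "token_prob", "entropy_bits",
        "perplexity", "expressed_conf_norm", "parse_status",
    ]
    out = graded[cols].copy()
    for c in ("token_prob", "entropy_bits", "perplexity", "expressed_conf_norm"):
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else f"{float(v):.6g}")
    out.to_csv(path, index=False)


def compare_prompt_variants(configs: list[RunConfig]) -> pd.DataFrame:
    """Token-probability AUROC per prompt variant, DeLong-tested vs baseline.

    The first config is the baseline (normally the vanilla prompt).  All
    variants must cover the same item set; the DeLong comparison is
    paired on item_id.
    """
    if len(configs) < 2:
        raise ValueError("need at least two variants to compare")
    runs = []
    for cfg in configs:
        items = read_mcq_dataset(cfg.dataset_path)
        records = read_response_log(cfg.response_log_path)
        graded, _ = grade_log(items, records, cfg.confidence_scale_max)
        sub = _metric_frame(graded, "token_prob").set_index("item_id").sort_index()
        label = cfg.label or (
            graded["prompt_variant"].iloc[0] if not graded.empty else "variant"
        )
        runs.append((label, sub, cfg))
    base_label, base, base_cfg = runs[0]
    rows = []
    for label, sub, cfg in runs:
        if not sub.index.equals(base.index):
            raise ValueError(
                f"variant {label!r} covers a different item set than the "
                f"baseline {base_label!r}"
            )
        roc = roc_and_auc(sub["score"], sub["correct"], cfg.ci_level)
        if label == base_label and sub is base:
            p = None
        else:
            _, _, _, p = delong_paired_test(
                sub["score"].to_numpy(),
                base["score"].to_numpy(),
                sub["correct"].to_numpy(dtype=bool),
            )
        rows.append(
            {
                "variant": label,
                "n": len(sub),
                "auroc": roc.auc,
                "auroc_ci_low": roc.auc_ci[0],
                "auroc_ci_high": roc.auc_ci[1],
                "delong_p_vs_baseline": p,
            }
        )
    return pd.DataFrame(rows)
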