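"""Synthetic multiple-choice items and LLM answer logs with known truth.

The generator emulates the regime observed when medical-licensing-exam
questions are posed to chat models through an API: answers follow the
fixed response template exactly, the option-token probability
distribution is concentrated when the model is right and dispersed when
it is wrong, and the verbalized confidence clusters high (in multiples
of 5) and carries little information about correctness.

Correctness is drawn first (Bernoulli at the target accuracy) and the
latent confidence conditioned on it.  In ``binormal`` mode the latent
score is Normal(mu, 1) for correct answers and Normal(0, 1) for
incorrect ones, mapped to (0, 1) by the logistic function — which gives
the closed-form true AUC Phi(mu / sqrt(2)) for recovery tests.
``dirichlet`` mode instead draws ragged option distributions from a
Dirichlet concentrated on the answered letter.

Defaults emulate a strong commercial model on a USMLE-style question
bank: 2500 five-option items, 75% accuracy, latent separation
mu = 1.4652 (true AUC 0.85), and a constant verbalized confidence of 95.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field
from scipy.special import expit, logit
from scipy.stats import norm

from .types import OPTION_LETTERS, McqItem, PromptVariant, ResponseRecord, TokenStep

__all__ = [
    "SimulatorConfig",
    "simulate_items",
    "simulate_responses",
    "true_auc",
    "expected_expressed_ace",
]

# Log-probability assigned to filler alternatives of deterministic tokens:
# effectively zero mass, but finite so records validate.
_FILLER_LOGP = -40.0


class SimulatorConfig(BaseModel):
    """Study conditions for one simulated model/dataset run."""

    n_items: int = Field(default=2500, ge=0)
    n_options: int = Field(default=5, ge=2, le=5)
    target_accuracy: float = Field(default=0.75, gt=0.0, le=1.0)
    discrimination_mode: Literal["binormal", "dirichlet"] = "binormal"
    binormal_mu: float = Field(default=1.4652, ge=0.0)
    dirichlet_skill: float = Field(default=4.0, gt=0.0)
    overconfidence_offset: float = Field(default=0.0, ge=-1.0, le=1.0)
    expressed_profile: Literal["constant_high", "quantized_informative"] = (
        "constant_high"
    )
    expressed_base: float = Field(default=95.0, ge=0.0, le=100.0)
    temperature_label: float = Field(default=0.0, ge=0.0)
    top_k: int = Field(default=5, ge=1)
    seed: int = 0
    model_tag: str = "synthetic-llm"
    prompt_variant: PromptVariant = "vanilla"
    dataset_tag: str = "synthetic-usmle"
    language_tag: str = "en"


def _rngs(config: SimulatorConfig) -> tuple[np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence(config.seed)
    child_items, child_resp = ss.spawn(2)
    return np.random.default_rng(child_items), np.random.default_rng(child_resp)


def simulate_items(config: SimulatorConfig) -> list[McqItem]:
    """Placeholder MCQ items with a uniformly drawn gold letter."""
    rng, _ = _rngs(config)
    letters = OPTION_LETTERS[: config.n_options]
    items = []
    for i in range(config.n_items):
        gold = letters[rng.integers(0, config.n_options)]
        items.append(
            McqItem(
                item_id=f"synth-{i:06d}",
                stem=f"Synthetic clinical vignette #{i}. Which option is correct?",
                options={L: f"Option {L} text" for L in letters},
                gold=gold,
                dataset_tag=config.dataset_tag,
                language_tag=config.language_tag,
            )
        )
    return items


def _round5(x: float) -> float:
    return 5.0 * round(x / 5.0)


def _format_confidence(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else f"{value:g}"


def _deterministic_step(token: str, k: int) -> TokenStep:
    top = [(token, 0.0)] + [(f"<alt{i}>", _FILLER_LOGP) for i in range(1, k)]
    return TokenStep(token=token, top_k=top)


def _answer_step(
    letter: str, option_probs: dict[str, float], k: int
) -> TokenStep:
    """Top-k list at the answer position encoding the option distribution."""
    entries = sorted(option_probs.items(), key=lambda kv: -kv[1])
    if len(entries) > k:
        kept = entries[: k - 1]
        if all(tok != letter for tok, _ in kept):
            kept.append((letter, option_probs[letter]))
        else:
            kept.append(entries[k - 1])
        entries = sorted(kept, key=lambda kv: -kv[1])
    top = [(f" {tok}", math.log(max(p, 1e-300))) for tok, p in entries]
    while len(top) < k:
        top.append((f"<alt{len(top)}>", _FILLER_LOGP))
    top.sort(key=lambda e: -e[1])
    return TokenStep(token=f" {letter}", top_k=top)


def _template_steps(
    letter: str, conf_text: str, option_probs: dict[str, float], k: int
) -> tuple[str, list[TokenStep]]:
    tokens = [
        "The", " correct", " answer", " is", ":",
        None,  # answer-letter slot
        ".", " My", " confidence", " level", " is", ":",
        f" {conf_text}", ".",
    ]
    steps: list[TokenStep] = []
    for tok in tokens:
        if tok is None:
            steps.append(_answer_step(letter, option_probs, k))
        else:
            steps.append(_deterministic_step(tok, k))
    raw_text = "".join(s.token for s in steps)
    return raw_text, steps


def simulate_responses(
    items: list[McqItem], config: SimulatorConfig
) -> list[ResponseRecord]:
    """Templated answer logs with configurable accuracy and discrimination.

    Per item: correctness ~ Bernoulli(target accuracy); the chosen letter
    is the gold letter when correct, uniform among the rest otherwise;
    the answer-token top-k encodes the option distribution (latent score
    on the chosen letter, remainder split evenly in binormal mode; a
    Dirichlet draw in dirichlet mode); every other token has probability
    1.  Expressed confidence is either the constant base value or the
    latent score plus the overconfidence offset, quantized to multiples
    of 5 and clipped to [0, 100].
    """
    _, rng = _rngs(config)
    m = config.n_options
    letters = OPTION_LETTERS[:m]
    records: list[ResponseRecord] = []
    for item in items:
        correct = rng.random() < config.target_accuracy
        if correct:
            letter = item.gold
        else:
            others = [L for L in letters if L != item.gold]
            letter = others[rng.integers(0, len(others))]

        if config.discrimination_mode == "binormal":
            z = rng.normal(config.binormal_mu if correct else 0.0, 1.0)
            s = float(expit(z))
            rest = (1.0 - s) / (m - 1)
            option_probs = {L: (s if L == letter else rest) for L in letters}
        else:
            alpha = np.ones(m)
            alpha[letters.index(letter)] = config.dirichlet_skill
            p = rng.dirichlet(alpha)
            option_probs = {L: float(p[i]) for i, L in enumerate(letters)}
            s = option_probs[letter]

        if config.expressed_profile == "constant_high":
            expressed = config.expressed_base
        else:
            expressed = min(
                100.0,
                max(0.0, _round5(100.0 * (s + config.overconfidence_offset))),
            )

        raw_text, steps = _template_steps(
            letter, _format_confidence(expressed), option_probs, config.top_k
        )
        records.append(
            ResponseRecord(
                item_id=item.item_id,
                raw_text=raw_text,
                token_steps=steps,
                temperature=config.temperature_label,
                model_tag=config.model_tag,
                prompt_variant=config.prompt_variant,
            )
        )
    return records


def true_auc(config: SimulatorConfig) -> float:
    """Closed-form AUC of the latent token-probability score.

    In binormal mode the latent score is Normal(mu, 1) vs Normal(0, 1)
    and the logistic map is strictly monotone, so the AUC of the mapped
    score is Phi(mu / sqrt(2)).  Dirichlet mode has no closed form.
    """
    if config.discrimination_mode != "binormal":
        raise ValueError("no closed form: true_auc requires binormal mode")
    return float(norm.cdf(config.binormal_mu / math.sqrt(2.0)))


def expected_expressed_ace(
    config: SimulatorConfig, n_bins: int = 10, grid: int = 20
) -> float:
    """Population (infinite-n) ACE of the quantized expressed confidence.

    Computes, by exact normal-CDF integration, the joint distribution of
    the quantized confidence value and correctness under the binormal
    generator, then applies the equal-mass binning to that population
    (atoms spanning a bin boundary are split proportionally).  Serves as
    the analytic oracle for calibration-recovery tests, independent of
    any sampled dataset.
    """
    if config.discrimination_mode != "binormal":
        raise ValueError("population ACE requires binormal mode")
    if config.expressed_profile != "quantized_informative":
        raise ValueError("population ACE applies to the quantized profile")
    a = config.target_accuracy
    mu = config.binormal_mu
    delta = config.overconfidence_offset

    # Confidence atoms v_k = k/grid; quantization maps s to v_k when
    # s + delta falls in [v_k - 1/(2*grid), v_k + 1/(2*grid)), with the
    # edge atoms absorbing the clipped tails.
    half = 0.5 / grid
    values = np.arange(grid + 1) / grid
    mass = np.zeros(grid + 1)
    mass_correct = np.zeros(grid + 1)
    for k, v in enumerate(values):
        lo_s = (v - half) - delta if k > 0 else -np.inf
        hi_s = (v + half) - delta if k < grid else np.inf
        lo_s = min(max(lo_s, 0.0), 1.0) if np.isfinite(lo_s) else lo_s
        hi_s = min(max(hi_s, 0.0), 1.0) if np.isfinite(hi_s) else hi_s

        def _cdf_z(sv, shift):
            if not np.isfinite(sv):
                return 0.0 if sv < 0 else 1.0
            if sv <= 0.0:
                return 0.0
            if sv >= 1.0:
                return 1.0
            return float(norm.cdf(logit(sv) - shift))

        p_c = _cdf_z(hi_s, mu) - _cdf_z(lo_s, mu)
        p_i = _cdf_z(hi_s, 0.0) - _cdf_z(lo_s, 0.0)
        mass[k] = a * p_c + (1 - a) * p_i
        mass_correct[k] = a * p_c
    mass_sum = mass.sum()
    mass /= mass_sum
    mass_correct /= mass_sum

    # Equal-mass binning of the population: bin b covers the cumulative
    # mass interval [b/B, (b+1)/B]; discrete atoms split across edges.
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    cum = np.concatenate([[0.0], np.cumsum(mass)])
    gaps = []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        w_conf = 0.0
        w_acc = 0.0
        w_tot = 0.0
        for k in range(grid + 1):
            overlap = max(0.0, min(cum[k + 1], hi) - max(cum[k], lo))
            if overlap <= 0.0 or mass[k] == 0.0:
                continue
            frac = overlap / mass[k]
            w_tot += overlap
            w_conf += overlap * values[k]
            w_acc += frac * mass_correct[k]
        if w_tot <= 0:
            continue
        gaps.append(abs(w_acc / w_tot - w_conf / w_tot))
    return float(np.mean(gaps))
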