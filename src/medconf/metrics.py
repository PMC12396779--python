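"""Per-answer confidence signals from token-level log-probabilities.

Four signals are computed for each answer:

* **response token probability** — the raw probability of the chosen
  option-letter token, NOT renormalized over the options (the simplest
  measure available to an API end user);
* **Shannon entropy** (bits) of the option-token distribution, with the
  unassigned top-k mass carried as one extra outcome;
* **answer perplexity** — the product over all emitted tokens of the
  reciprocal of each token's probability, computed in log space;
* **normalized expressed confidence** — the verbalized self-rating
  divided by its scale maximum.

Entropy and perplexity are doubt measures (higher = less confident);
discrimination code negates them so every score is oriented
higher-is-more-confident.
"""

from __future__ import annotations

import math

from scipy.stats import entropy as _scipy_entropy

from .parsing import strip_token
from .types import (
    OptionTokenDistribution,
    ParsedAnswer,
    ResponseRecord,
    UncertaintyScores,
)


def build_option_distribution(
    record: ResponseRecord, answer_index: int, option_letters: tuple[str, ...]
) -> OptionTokenDistribution:
    """Option-letter probabilities from the top-k list at the answer position.

    Each option letter gets exp(log-probability) of its best-matching
    top-k entry (same token-stripping rule as answer location), or 0 when
    absent from the top-k; leftover mass is recorded as ``residual_mass``.
    """
    if not 0 <= answer_index < len(record.token_steps):
        raise IndexError(
            f"answer_index {answer_index} outside record of length "
            f"{len(record.token_steps)}"
        )
    step = record.token_steps[answer_index]
    probs: dict[str, float] = {letter: 0.0 for letter in option_letters}
    assigned: set[str] = set()
    # top_k is sorted by descending log-probability, so the first match
    # per letter is the best one.
    for tok, logp in step.top_k:
        letter = strip_token(tok)
        if letter in probs and letter not in assigned:
            probs[letter] = math.exp(logp)
            assigned.add(letter)
    chosen = strip_token(step.token)
    if chosen in probs and chosen not in assigned:
        raise ValueError(
            f"chosen letter {chosen!r} absent from top_k at answer position"
        )
    option_mass = sum(probs.values())
    if option_mass > 1 + 1e-6:
        raise ValueError(f"option-letter probabilities sum to {option_mass} > 1")
    residual = max(0.0, 1.0 - option_mass)
    return OptionTokenDistribution(
        probs=probs, residual_mass=residual, source_k=len(step.top_k)
    )


def response_token_probability(dist: OptionTokenDistribution, letter: str) -> float:
    """Raw probability of the chosen letter; never renormalized."""
    if letter not in dist.probs:
        raise KeyError(f"letter {letter!r} not in option distribution")
    return dist.probs[letter]


def shannon_entropy_bits(dist: OptionTokenDistribution) -> float:
    """Entropy (base 2) over option letters plus the residual pseudo-outcome."""
    pk = list(dist.probs.values()) + [dist.residual_mass]
    return float(_scipy_entropy(pk, base=2))


def answer_perplexity(record: ResponseRecord, length_normalized: bool = False) -> float:
    """Perplexity of the emitted answer: prod over tokens of 1/p_t.

    Computed in log space as exp(-sum ln p_t); no length normalization by
    default.  With ``length_normalized=True`` the per-token geometric-mean
    variant exp(-(1/T) sum ln p_t) is returned instead.
    """
    total = 0.0
    for step in record.token_steps:
        lp = step.emitted_logprob
        if not math.isfinite(lp):
            raise ValueError(
                f"emitted token {step.token!r} has non-finite log-probability"
            )
        total += lp
    if length_normalized:
        total /= len(record.token_steps)
    return math.exp(-total)


def normalize_expressed_confidence(parsed: ParsedAnswer) -> float:
    """Expressed confidence rescaled to [0, 1] (value / scale max)."""
    if parsed.expressed_confidence is None:
        raise ValueError(
            f"record {parsed.item_id!r} has no expressed confidence; exclude "
            "it from expressed-confidence analyses instead of scoring it"
        )
    return parsed.expressed_confidence / parsed.confidence_scale_max


def score_answer(
    record: ResponseRecord,
    parsed: ParsedAnswer,
    option_letters: tuple[str, ...],
    answer_index: int,
) -> UncertaintyScores:
    """All four signals for one answer (token-position already located)."""
    dist = build_option_distribution(record, answer_index, option_letters)
    expressed = (
        normalize_expressed_confidence(parsed)
        if parsed.expressed_confidence is not None
        else None
    )
    assert parsed.letter is not None
    return UncertaintyScores(
        token_prob=response_token_probability(dist, parsed.letter),
        entropy_bits=shannon_entropy_bits(dist),
        perplexity=answer_perplexity(record),
        expressed_conf_norm=expressed,
    )
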