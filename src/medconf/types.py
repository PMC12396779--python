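"""Core domain types for multiple-choice QA confidence evaluation.

The containers here mirror the shape of the raw artifacts of a
model-evaluation run: the question items, the per-token answer logs
(with top-k log-probabilities as returned by LLM APIs), and the parsed
and scored answers derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

OPTION_LETTERS: tuple[str, ...] = ("A", "B", "C", "D", "E")

PromptVariant = Literal["vanilla", "expert", "confidence_scaling", "few_shot"]

ParseStatus = Literal["template", "fallback", "failed"]


class McqItem(BaseModel):
    """One multiple-choice question with 2-5 lettered options."""

    item_id: str
    stem: str
    options: dict[str, str]
    gold: str
    dataset_tag: str = ""
    language_tag: str = ""

    @model_validator(mode="before")
    @classmethod
    def _normalize_letters(cls, data):
        if isinstance(data, dict):
            opts = data.get("options")
            if isinstance(opts, dict):
                data = dict(data)
                data["options"] = {str(k).strip().upper(): v for k, v in opts.items()}
            gold = data.get("gold")
            if isinstance(gold, str):
                data["gold"] = gold.strip().upper()
        return data

    @model_validator(mode="after")
    def _check_options(self) -> "McqItem":
        letters = list(self.options)
        if not 2 <= len(letters) <= 5:
            raise ValueError(
                f"item {self.item_id!r}: expected 2-5 options, got {len(letters)}"
            )
        expected = list(OPTION_LETTERS[: len(letters)])
        if sorted(letters) != expected:
            raise ValueError(
                f"item {self.item_id!r}: option letters must be consecutive "
                f"from A, got {sorted(letters)}"
            )
        if self.gold not in self.options:
            raise ValueError(
                f"item {self.item_id!r}: gold letter {self.gold!r} not among "
                f"options {sorted(letters)}"
            )
        return self

    @property
    def letters(self) -> tuple[str, ...]:
        return tuple(OPTION_LETTERS[: len(self.options)])


class TokenStep(BaseModel):
    """One generated token and the top-k log-probability list at its position.

    Log-probabilities are natural-log, as emitted by LLM APIs; they are
    converted to probabilities only inside metric code.
    """

    token: str
    top_k: list[tuple[str, float]] = Field(min_length=1)

    @model_validator(mode="after")
    def _check_top_k(self) -> "TokenStep":
        logps = [lp for _, lp in self.top_k]
        for lp in logps:
            if lp > 0.0:
                raise ValueError(
                    f"positive log-probability {lp} for token {self.token!r}"
                )
        if any(a < b for a, b in zip(logps, logps[1:])):
            raise ValueError(
                f"top_k not sorted by descending log-probability at token "
                f"{self.token!r}"
            )
        if self.token not in {t for t, _ in self.top_k}:
            raise ValueError(
                f"emitted token {self.token!r} missing from its own top_k"
            )
        return self

    @property
    def emitted_logprob(self) -> float:
        """Natural-log probability of the emitted token."""
        for tok, lp in self.top_k:
            if tok == self.token:
                return lp
        raise AssertionError("unreachable: validated at construction")


class ResponseRecord(BaseModel):
    """One raw model answer: response text plus per-token top-k log-probs."""

    item_id: str
    raw_text: str
    token_steps: list[TokenStep] = Field(min_length=1)
    temperature: float = Field(default=0.0, ge=0.0)
    model_tag: str = ""
    prompt_variant: PromptVariant = "vanilla"

    @model_validator(mode="after")
    def _check_constant_k(self) -> "ResponseRecord":
        ks = {len(s.top_k) for s in self.token_steps}
        if len(ks) > 1:
            raise ValueError(
                f"record {self.item_id!r}: top_k depth must be constant within "
                f"a record, got depths {sorted(ks)}"
            )
        return self

    @property
    def top_k_depth(self) -> int:
        return len(self.token_steps[0].top_k)


class ParsedAnswer(BaseModel):
    """Chosen option letter and expressed confidence extracted from raw text."""

    item_id: str = ""
    letter: Optional[str] = None
    expressed_confidence: Optional[float] = None
    confidence_scale_max: Literal[100, 1] = 100
    parse_status: ParseStatus = "failed"

    @field_validator("letter")
    @classmethod
    def _check_letter(cls, v):
        if v is not None and v not in OPTION_LETTERS:
            raise ValueError(f"letter must be one of {OPTION_LETTERS}, got {v!r}")
        return v

    @model_validator(mode="after")
    def _check_consistency(self) -> "ParsedAnswer":
        if self.parse_status == "template":
            if self.letter is None or self.expressed_confidence is None:
                raise ValueError(
                    "template parse requires both letter and confidence"
                )
        if self.parse_status == "failed":
            if self.letter is not None or self.expressed_confidence is not None:
                raise ValueError("failed parse must carry no letter/confidence")
        if self.expressed_confidence is not None and not (
            0.0 <= self.expressed_confidence <= self.confidence_scale_max
        ):
            raise ValueError(
                f"expressed confidence {self.expressed_confidence} outside "
                f"[0, {self.confidence_scale_max}]"
            )
        return self


@dataclass(frozen=True)
class OptionTokenDistribution:
    """Probabilities over option letters at the answer-token position.

    ``residual_mass`` is whatever top-k probability was not assigned to any
    option letter; it is carried as a single extra outcome so the
    distribution stays proper.
    """

    probs: dict[str, float]
    residual_mass: float
    source_k: int

    def __post_init__(self):
        total = sum(self.probs.values()) + self.residual_mass
        if self.residual_mass < -1e-12:
            raise ValueError(f"negative residual mass {self.residual_mass}")
        if not (1 - 1e-6 <= total <= 1 + 1e-6):
            raise ValueError(f"option distribution mass {total} not ~1")


@dataclass(frozen=True)
class UncertaintyScores:
    """The per-answer confidence signals.

    ``token_prob`` is the raw (unnormalized) probability of the chosen
    letter token.  ``entropy_bits`` and ``perplexity`` are doubt-oriented
    (higher = less confident); discrimination code negates them.
    ``expressed_conf_norm`` is the verbalized confidence rescaled to [0, 1],
    or None when the model gave no usable confidence number.
    """

    token_prob: Optional[float] = None
    entropy_bits: Optional[float] = None
    perplexity: Optional[float] = None
    expressed_conf_norm: Optional[float] = None


@dataclass(frozen=True)
class GradedAnswer:
    """One parsed answer joined with its gold letter and scores."""

    item_id: str
    correct: bool
    scores: UncertaintyScores
    letter: Optional[str] = None
    gold: Optional[str] = None
    parse_status: ParseStatus = "template"
    expressed_confidence: Optional[float] = None
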