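"""Extracting the chosen letter and expressed confidence from model output.

Models are prompted to answer with the fixed template

    The correct answer is: [letter]. My confidence level is: [number].

The template branch matches that phrasing case-insensitively with
flexible whitespace.  Responses that ignore the template go through a
deterministic rule-based fallback (first standalone option letter, first
number within the confidence scale); responses that defeat both are
marked ``failed`` and excluded from metric denominators downstream.
"""

from __future__ import annotations

import re

from .types import OPTION_LETTERS, ParsedAnswer, ResponseRecord

_NUMBER = r"(\d+(?:\.\d+)?)"

_TEMPLATE_RE = re.compile(
    r"the\s+correct\s+answer\s+is\s*:?\s*[\(\[]?([A-Ea-e])[\)\]]?\s*[.,;]?"
    r"\s+my\s+confidence\s+level\s+is\s*:?\s*" + _NUMBER + r"\s*%?\s*\.?",
    re.IGNORECASE,
)

# Standalone uppercase option letter.  Restricted to uppercase so the
# English article "a" in free text never counts as an answer.
_FALLBACK_LETTER_RE = re.compile(r"\b([A-E])\b")

_FALLBACK_NUMBER_RE = re.compile(r"(?<![\w.])" + _NUMBER + r"(?![\w])")


class AnswerTokenNotFoundError(LookupError):
    """The chosen letter was never emitted as a token."""


def parse_response(raw_text: str, confidence_scale_max: int = 100) -> ParsedAnswer:
    """Parse one raw response into letter + expressed confidence.

    Returns a :class:`ParsedAnswer` whose ``parse_status`` is ``template``
    when the prompt template matched, ``fallback`` when only the
    rule-based scan found a letter, and ``failed`` otherwise.  Parse
    failure is a status, never an exception.
    """
    m = _TEMPLATE_RE.search(raw_text)
    if m:
        letter = m.group(1).upper()
        conf = float(m.group(2))
        if 0.0 <= conf <= confidence_scale_max:
            return ParsedAnswer(
                letter=letter,
                expressed_confidence=conf,
                confidence_scale_max=confidence_scale_max,
                parse_status="template",
            )
        # Template phrasing but an out-of-scale number: keep the letter,
        # drop the confidence, and demote to fallback status.
        return ParsedAnswer(
            letter=letter,
            expressed_confidence=None,
            confidence_scale_max=confidence_scale_max,
            parse_status="fallback",
        )

    lm = _FALLBACK_LETTER_RE.search(raw_text)
    if lm is None:
        return ParsedAnswer(
            confidence_scale_max=confidence_scale_max, parse_status="failed"
        )
    letter = lm.group(1)
    conf = None
    for nm in _FALLBACK_NUMBER_RE.finditer(raw_text):
        value = float(nm.group(1))
        if 0.0 <= value <= confidence_scale_max:
            conf = value
            break
    return ParsedAnswer(
        letter=letter,
        expressed_confidence=conf,
        confidence_scale_max=confidence_scale_max,
        parse_status="fallback",
    )


_STRIP_LEADING = " \t([" + '"' + "'"
_STRIP_TRAILING = " \t.):,;]" + '"' + "'"


def strip_token(token: str) -> str:
    """Normalize a token for letter matching across tokenizer dialects.

    Different model families emit the answer letter as "B", " B", "B.",
    "(B", etc.; leading whitespace/brackets and trailing punctuation are
    stripped before comparison.
    """
    return token.lstrip(_STRIP_LEADING).rstrip(_STRIP_TRAILING)


def locate_answer_token(record: ResponseRecord, letter: str) -> int:
    """Index of the first emitted token matching the chosen letter.

    The top-k list at that position defines the option-token
    distribution.  Raises :class:`AnswerTokenNotFoundError` when the
    letter was never emitted; callers flag such records and exclude them
    from token-probability analyses.
    """
    if letter not in OPTION_LETTERS:
        raise ValueError(f"letter must be one of {OPTION_LETTERS}, got {letter!r}")
    for idx, step in enumerate(record.token_steps):
        if strip_token(step.token) == letter:
            return idx
    raise AnswerTokenNotFoundError(
        f"answer token not found: letter {letter!r} never emitted in record "
        f"{record.item_id!r}"
    )
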