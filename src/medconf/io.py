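"""Reading and writing QA datasets, model answer logs, and report tables.

Canonical on-disk formats are plain text:

* datasets: JSONL (one item per line) or flat CSV;
* answer logs: JSONL only, because the nested per-token top-k
  log-probability lists do not fit a flat CSV;
* reports: CSV with a deterministic column order and numbers written to
  six significant digits.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

from pydantic import ValidationError

from .types import OPTION_LETTERS, McqItem, ResponseRecord

logger = logging.getLogger(__name__)

_DATASET_CSV_COLUMNS = (
    "item_id",
    "stem",
    "option_A",
    "option_B",
    "option_C",
    "option_D",
    "option_E",
    "gold",
    "dataset_tag",
    "language_tag",
)


class DatasetFormatError(ValueError):
    """A dataset or log file failed validation; message names the line."""


def _format_validation_error(err: ValidationError) -> str:
    parts = []
    for e in err.errors():
        loc = ".".join(str(x) for x in e["loc"]) or "record"
        parts.append(f"{loc}: {e['msg']}")
    return "; ".join(parts)


def read_mcq_dataset(path: str | Path, format_name: str | None = None) -> list[McqItem]:
    """Read a multiple-choice dataset from JSONL or CSV, in file order.

    Each record must carry item_id, stem, options and gold; invariants
    (2-5 consecutive letters from A, gold among them) are validated per
    item, and a malformed record raises :class:`DatasetFormatError`
    naming the line number.  Duplicate item_ids are an error.
    """
    path = Path(path)
    if format_name is None:
        format_name = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format_name not in ("jsonl", "csv"):
        raise ValueError(f"unknown dataset format {format_name!r}")

    items: list[McqItem] = []
    seen: set[str] = set()

    def _add(item: McqItem, lineno: int) -> None:
        if item.item_id in seen:
            raise DatasetFormatError(
                f"{path}:{lineno}: duplicate item_id {item.item_id!r}"
            )
        seen.add(item.item_id)
        items.append(item)

    if format_name == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    raw = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise DatasetFormatError(
                        f"{path}:{lineno}: invalid JSON: {exc}"
                    ) from exc
                try:
                    item = McqItem.model_validate(raw)
                except ValidationError as exc:
                    raise DatasetFormatError(
                        f"{path}:{lineno}: {_format_validation_error(exc)}"
                    ) from exc
                _add(item, lineno)
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            missing = {"item_id", "stem", "gold"} - set(reader.fieldnames)
            if missing:
                raise DatasetFormatError(
                    f"{path}:1: missing columns {sorted(missing)}"
                )
            for lineno, row in enumerate(reader, start=2):
                options = {
                    letter: row[f"option_{letter}"]
                    for letter in OPTION_LETTERS
                    if row.get(f"option_{letter}", "") != ""
                }
                raw = {
                    "item_id": row["item_id"],
                    "stem": row["stem"],
                    "options": options,
                    "gold": row["gold"],
                    "dataset_tag": row.get("dataset_tag", ""),
                    "language_tag": row.get("language_tag", ""),
                }
                try:
                    item = McqItem.model_validate(raw)
                except ValidationError as exc:
                    raise DatasetFormatError(
                        f"{path}:{lineno}: {_format_validation_error(exc)}"
                    ) from exc
                _add(item, lineno)
    return items


def write_mcq_dataset(
    items: Iterable[McqItem], path: str | Path, format_name: str | None = None
) -> None:
    """Write a dataset as JSONL (default) or CSV."""
    path = Path(path)
    if format_name is None:
        format_name = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format_name == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for item in items:
                fh.write(json.dumps(item.model_dump(), ensure_ascii=False) + "\n")
    elif format_name == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_DATASET_CSV_COLUMNS)
            writer.writeheader()
            for item in items:
                row = {
                    "item_id": item.item_id,
                    "stem": item.stem,
                    "gold": item.gold,
                    "dataset_tag": item.dataset_tag,
                    "language_tag": item.language_tag,
                }
                for letter in OPTION_LETTERS:
                    row[f"option_{letter}"] = item.options.get(letter, "")
                writer.writerow(row)
    else:
        raise ValueError(f"unknown dataset format {format_name!r}")


def read_response_log(path: str | Path) -> list[ResponseRecord]:
    """Read a JSONL model answer log, preserving file order.

    Validation enforces the log-probability invariants (each value <= 0,
    top-k sorted descending, emitted token present in its own top-k,
    constant top-k depth within a record).  Duplicate
    (item_id, model_tag, prompt_variant) records are kept — downstream
    grading uses the first — and a warning is logged.
    """
    path = Path(path)
    records: list[ResponseRecord] = []
    seen: set[tuple[str, str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                raw = json.loads(line)
            except json.JSONDecodeError as exc:
                raise DatasetFormatError(
                    f"{path}:{lineno}: invalid JSON: {exc}"
                ) from exc
            if isinstance(raw, dict) and "token_steps" in raw:
                steps = raw["token_steps"]
                if isinstance(steps, list):
                    raw = dict(raw)
                    raw["token_steps"] = [
                        {"token": s["token"], "top_k": s["top_k"]}
                        if isinstance(s, dict)
                        else s
                        for s in steps
                    ]
            try:
                rec = ResponseRecord.model_validate(raw)
            except ValidationError as exc:
                raise DatasetFormatError(
                    f"{path}:{lineno}: {_format_validation_error(exc)}"
                ) from exc
            key = (rec.item_id, rec.model_tag, rec.prompt_variant)
            if key in seen:
                logger.warning(
                    "%s:%d: duplicate record for item_id=%r model=%r "
                    "variant=%r kept; grading uses the first occurrence",
                    path,
                    lineno,
                    rec.item_id,
                    rec.model_tag,
                    rec.prompt_variant,
                )
            seen.add(key)
            records.append(rec)
    return records


def write_response_log(records: Iterable[ResponseRecord], path: str | Path) -> None:
    """Write an answer log as JSONL (inverse of :func:`read_response_log`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            obj = {
                "item_id": rec.item_id,
                "model_tag": rec.model_tag,
                "prompt_variant": rec.prompt_variant,
                "temperature": rec.temperature,
                "raw_text": rec.raw_text,
                "token_steps": [
                    {"token": s.token, "top_k": [[t, lp] for t, lp in s.top_k]}
                    for s in rec.token_steps
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def format_sig(value) -> str:
    """Render a number to 6 significant digits; pass strings/None through."""
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, (int,)):
        return str(value)
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_report_tables(reports: Sequence, out_dir: str | Path) -> set[Path]:
    """Write report objects as CSV files, one file per report kind.

    Any object exposing ``report_kind`` (a file stem) and ``report_rows()``
    (an iterable of dicts with a stable key order) is accepted; rows of
    reports sharing a kind are concatenated into the same file.  Returns
    the set of paths written.  An empty report list writes nothing.
    """
    out_dir = Path(out_dir)
    if reports:
        out_dir.mkdir(parents=True, exist_ok=True)
    grouped: dict[str, list[dict]] = {}
    for report in reports:
        kind = getattr(report, "report_kind", None)
        rows = getattr(report, "report_rows", None)
        if kind is None or rows is None:
            raise TypeError(
                f"object {type(report).__name__} is not a report "
                "(needs report_kind and report_rows())"
            )
        grouped.setdefault(kind, []).extend(rows())
    written: set[Path] = set()
    for kind, rows in grouped.items():
        path = out_dir / f"{kind}.csv"
        if not rows:
            continue
        fieldnames = list(rows[0].keys())
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fieldnames)
            writer.writeheader()
            for row in rows:
                writer.writerow({k: format_sig(v) for k, v in row.items()})
        written.add(path)
    return written
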