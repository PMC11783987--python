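"""Reading and writing recall protocols.

Two on-disk formats are supported, both UTF-8 text:

``tsv``
    One trial per row, tab-separated, with a header line.  Columns:
    ``trial_id``, ``condition``, ``list_length``, ``presented``
    (semicolon-joined item tokens) and ``recalled`` (semicolon-joined
    response tokens; may be empty).  The reserved token ``blank`` marks an
    explicit omission; any other token not in ``presented`` is an
    intrusion.

``letters``
    Two tab-separated columns per line — presented letters and recalled
    letters — one trial per line, e.g. ``ABCDEFGH<TAB>GFAC``.  ``-`` marks
    an omission.  An optional third column carries a condition label.

Round trip is token-exact: ``read_trials(write_trials(ts)) == ts``.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .model import (
    OMISSION_CHAR,
    OMISSION_TOKEN,
    EventKind,
    Trial,
    TrialSet,
    parse_letter_trial,
    render_letter_trial,
    trial_from_tokens,
)

__all__ = ["read_trials", "write_trials", "TrialFormatError"]

_TSV_COLUMNS = ["trial_id", "condition", "list_length", "presented", "recalled"]


class TrialFormatError(ValueError):
    """Malformed protocol file; message lists offending line numbers."""


def _split_tokens(cell: str) -> list[str]:
    return cell.split(";") if cell else []


def _read_tsv(path: Path, omission_token: str) -> TrialSet:
    trials: list[Trial] = []
    errors: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TrialFormatError(f"{path}: empty file")
        missing = [c for c in _TSV_COLUMNS if c not in header]
        if missing:
            raise TrialFormatError(f"{path}: missing required columns {missing}")
        idx = {c: header.index(c) for c in _TSV_COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell for cell in row):
                continue
            try:
                presented = _split_tokens(row[idx["presented"]])
                recalled = _split_tokens(row[idx["recalled"]])
                declared = int(row[idx["list_length"]])
                if declared != len(presented):
                    raise ValueError(
                        f"list_length {declared} disagrees with "
                        f"{len(presented)} presented tokens"
                    )
                trials.append(
                    trial_from_tokens(
                        row[idx["trial_id"]],
                        row[idx["condition"]],
                        presented,
                        recalled,
                        omission_token=omission_token,
                    )
                )
            except (ValueError, IndexError) as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise TrialFormatError(f"{path}: " + "; ".join(errors))
    return TrialSet(trials=trials, metadata={"source": str(path), "format": "tsv"})


def _read_letters(path: Path, omission_char: str) -> TrialSet:
    trials: list[Trial] = []
    errors: list[str] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                errors.append(f"line {lineno}: expected two tab-separated columns")
                continue
            condition = parts[2] if len(parts) > 2 else ""
            try:
                trials.append(
                    parse_letter_trial(
                        parts[0],
                        parts[1],
                        trial_id=f"L{lineno}",
                        condition=condition,
                        omission_char=omission_char,
                    )
                )
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise TrialFormatError(f"{path}: " + "; ".join(errors))
    return TrialSet(trials=trials, metadata={"source": str(path), "format": "letters"})


def read_trials(
    path: str | Path,
    format: str = "tsv",
    *,
    omission_token: str = OMISSION_TOKEN,
    omission_char: str = OMISSION_CHAR,
) -> TrialSet:
    """Read a protocol file; ``format`` is ``"tsv"`` or ``"letters"``.

    Raises :class:`TrialFormatError` naming line numbers for malformed
    rows (duplicate presented tokens, list_length mismatches, missing
    columns).
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path, omission_token)
    if format == "letters":
        return _read_letters(path, omission_char)
    raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'letters')")


def write_trials(
    trials: TrialSet,
    path: str | Path,
    format: str = "tsv",
    *,
    omission_token: str = OMISSION_TOKEN,
    omission_char: str = OMISSION_CHAR,
) -> None:
    """Write a TrialSet; inverse of :func:`read_trials` at token level."""
    path = Path(path)
    if format == "tsv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(_TSV_COLUMNS)
            for t in trials:
                recalled = ";".join(
                    omission_token if e.kind is EventKind.OMISSION_MARK else e.raw_token
                    for e in t.recall_events
                )
                writer.writerow(
                    [t.trial_id, t.condition, t.list_length, ";".join(t.presented), recalled]
                )
    elif format == "letters":
        with path.open("w", encoding="utf-8") as fh:
            for t in trials:
                pres, rec = render_letter_trial(t, omission_char=omission_char)
                fh.write(f"{pres}\t{rec}\t{t.condition}\n")
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'letters')")
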