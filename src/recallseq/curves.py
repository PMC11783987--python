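"""Serial-position curves and transposition matrices.

Three correctness rules are supported:

* ``SR`` (serial-recall scoring) — item i is correct only when its first
  occurrence is output at output position i.  Output rank is the
  positional slot (spoken-recall convention): intrusions and explicit
  omission marks occupy an output index and shift later items' slots,
  while unmarked early termination does not back-fill.  This is exactly
  the convention under which recency items, output prematurely after
  earlier omissions, fail to score as correct.
* ``FR`` (free-recall scoring) — item i is correct when recalled at any
  output position.
* ``START_END`` — item i is correct only when its eligible occurrence is
  labelled START or END; completely correct trials score every item.

``OTHER_RESIDUAL`` curves plot the proportion of trials on which each
item was recalled as an Other item (in neither sequence); they are
recency-justified: distance 0 is the last list item.

Transposition matrices count, per trial, where each list item's first
occurrence was output: ``counts[i, o]``.  Intrusions and omission marks
occupy output indices but contribute no counts; repetitions beyond the
first occurrence are ignored.  The error-only gradient drops the
diagonal (i == o) and normalises the rest by the total number of order
errors, so cells sum to 1 whenever any order error exists.

Curves are computed per list length and never averaged across lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .model import EventKind, Trial, TrialSet
from .scoring import SequencePolicy, TrialAnnotation, annotate_trial

__all__ = [
    "PositionCurve",
    "TranspositionTable",
    "EmptyGradientError",
    "score_trial",
    "position_curve",
    "residual_other_curve",
    "transposition_matrix",
    "error_gradient",
]

Rule = Literal["SR", "FR", "START_END", "OTHER_RESIDUAL"]
Alignment = Literal["primacy", "recency"]


class EmptyGradientError(ValueError):
    """No order errors: the error-only gradient is undefined."""


@dataclass
class PositionCurve:
    """Mean correctness (or Other-recall) proportion per position.

    Under ``primacy`` alignment ``values[p]`` refers to input position
    p+1; under ``recency`` alignment ``values[d]`` refers to the item at
    distance d from the end of the list (d = 0 is item n).
    """

    rule: Rule
    alignment: Alignment
    list_length: int
    values: np.ndarray
    denominator: int

    def to_frame(self, condition: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": condition,
                "list_length": self.list_length,
                "rule": self.rule,
                "alignment": self.alignment,
                "position": np.arange(len(self.values)) + (self.alignment == "primacy"),
                "value": self.values,
                "denominator": self.denominator,
            }
        )


@dataclass
class TranspositionTable:
    """Counts (or proportions) indexed by (input position, output position).

    ``counts[i-1, o-1]``; output positions run 1..n_out where n_out is at
    least the list length (longer protocols extend the output axis).
    ``normalisation`` records what the cells mean.
    """

    n: int
    counts: np.ndarray
    normalisation: Literal["none", "by_input", "by_total_errors"] = "none"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)

    @property
    def n_out(self) -> int:
        return self.counts.shape[1]

    def proportions_by_input(self) -> "TranspositionTable":
        """Each row divided by its input position's total count."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            props = np.where(totals > 0, self.counts / totals, 0.0)
        return TranspositionTable(self.n, props, "by_input")

    def to_frame(self, condition: str = "", source: str = "observed") -> pd.DataFrame:
        i, o = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "condition": condition,
                "source": source,
                "list_length": self.n,
                "normalisation": self.normalisation,
                "input_position": i + 1,
                "output_position": o + 1,
                "value": self.counts[i, o],
            }
        )

    def to_csv(self, path: str | Path, **kwargs) -> None:
        self.to_frame(**kwargs).to_csv(path, index=False)


def _annotations_by_id(
    trials: TrialSet,
    annotations: Iterable[TrialAnnotation] | None,
    policy: SequencePolicy | None,
) -> dict[str, TrialAnnotation]:
    if annotations is None:
        return {t.trial_id: annotate_trial(t, policy) for t in trials}
    return {a.trial_id: a for a in annotations}


def _first_occurrence_outputs(trial: Trial) -> dict[int, int]:
    """input position -> output index of its first ITEM occurrence."""
    out: dict[int, int] = {}
    for e in trial.recall_events:
        if e.kind is EventKind.ITEM and e.input_position not in out:
            out[e.input_position] = e.output_index  # type: ignore[index]
    return out


def score_trial(
    trial: Trial, annotation: TrialAnnotation, rule: Rule
) -> np.ndarray:
    """Per-input-position 0/1 correctness indicators under ``rule``."""
    if annotation.trial_id != trial.trial_id:
        raise ValueError("annotation does not correspond to trial")
    n = trial.n
    correct = np.zeros(n, dtype=int)
    first = _first_occurrence_outputs(trial)
    if rule == "FR":
        for i in first:
            correct[i - 1] = 1
    elif rule == "SR":
        for i, o in first.items():
            if i == o:
                correct[i - 1] = 1
    elif rule == "START_END":
        if annotation.complete_correct:
            correct[:] = 1
        else:
            for j, e in enumerate(trial.recall_events):
                if annotation.event_labels[j] in ("START", "END"):
                    correct[e.input_position - 1] = 1  # type: ignore[index]
    else:
        raise ValueError(f"unknown scoring rule {rule!r}")
    return correct


def position_curve(
    trials: TrialSet,
    annotations: Iterable[TrialAnnotation] | None = None,
    rule: Rule = "SR",
    alignment: Alignment = "primacy",
    *,
    include_complete: bool = True,
    policy: SequencePolicy | None = None,
) -> dict[int, PositionCurve]:
    """Serial-position curves, one per list length present in ``trials``.

    ``include_complete=False`` drops completely correct trials before
    aggregating (the include/exclude contrast for start/end scoring).
    """
    if len(trials) == 0:
        raise ValueError("empty trial set")
    ann = _annotations_by_id(trials, annotations, policy)
    sums: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for t in trials:
        a = ann[t.trial_id]
        if not include_complete and a.complete_correct:
            continue
        v = score_trial(t, a, rule)
        sums.setdefault(t.n, np.zeros(t.n, dtype=float))
        sums[t.n] += v
        counts[t.n] = counts.get(t.n, 0) + 1
    out: dict[int, PositionCurve] = {}
    for n, s in sums.items():
        values = s / counts[n]
        if alignment == "recency":
            values = values[::-1]
        out[n] = PositionCurve(rule, alignment, n, values, counts[n])
    return out


def residual_other_curve(
    trials: TrialSet,
    annotations: Iterable[TrialAnnotation] | None = None,
    *,
    include_complete: bool = True,
    policy: SequencePolicy | None = None,
) -> dict[int, PositionCurve]:
    """Proportion of trials on which each item was recalled as 'Other'.

    Recency-justified: ``values[0]`` is the last list item (distance 0).
    Completely correct trials have no Other items and contribute zeros
    (when included).
    """
    if len(trials) == 0:
        raise ValueError("empty trial set")
    ann = _annotations_by_id(trials, annotations, policy)
    sums: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for t in trials:
        a = ann[t.trial_id]
        if not include_complete and a.complete_correct:
            continue
        v = np.zeros(t.n, dtype=float)
        for pos in set(a.other_positions):
            v[pos - 1] = 1.0
        sums.setdefault(t.n, np.zeros(t.n, dtype=float))
        sums[t.n] += v
        counts[t.n] = counts.get(t.n, 0) + 1
    return {
        n: PositionCurve("OTHER_RESIDUAL", "recency", n, (s / counts[n])[::-1], counts[n])
        for n, s in sums.items()
    }


def transposition_matrix(
    trials: TrialSet | Sequence[Trial],
) -> TranspositionTable:
    """Raw counts of (input position, output position) pairs.

    Only first occurrences of list items contribute; intrusions and
    omission marks occupy output indices but add no counts.  All trials
    must share one list length.
    """
    trial_list = list(trials)
    if not trial_list:
        raise ValueError("empty trial set")
    lengths = {t.n for t in trial_list}
    if len(lengths) != 1:
        raise ValueError(f"mixed list lengths {sorted(lengths)}: aggregate per length")
    n = lengths.pop()
    n_out = max([n] + [len(t.recall_events) for t in trial_list])
    counts = np.zeros((n, n_out), dtype=float)
    for t in trial_list:
        for i, o in _first_occurrence_outputs(t).items():
            counts[i - 1, o - 1] += 1
    return TranspositionTable(n, counts, "none")


def error_gradient(table: TranspositionTable) -> TranspositionTable:
    """Error-only gradient: diagonal removed, cells normalised by the
    total number of order errors (cells then sum to 1).

    Raises :class:`EmptyGradientError` when there are no order errors.
    """
    errors = table.counts.copy()
    d = min(table.n, table.n_out)
    errors[np.arange(d), np.arange(d)] = 0.0
    total = errors.sum()
    if total == 0:
        raise EmptyGradientError("no order errors: gradient undefined")
    return TranspositionTable(table.n, errors / total, "by_total_errors")
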