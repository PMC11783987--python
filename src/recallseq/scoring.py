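"""Start- and end-sequence detection and trial annotation.

A *start-sequence* is a run of recalls of items from consecutive input
serial positions, in forward order, initiating with the first list item;
an *end-sequence* is such a run terminating with the last list item.
Either run may sit anywhere in the output: for the 8-item list ABCDEFGH,
the recall FGHCABG contains an end-sequence of three (F,G,H at outputs
1-3) and a start-sequence of two (A,B at outputs 5-6).  A singleton
recall of item 1 (or item n) anywhere counts as a length-1 start (end)
sequence; the start length is 0 exactly when item 1 is never recalled as
an eligible occurrence, and symmetrically for the end.

Scoring policy (see :class:`SequencePolicy`):

* ``first_occurrence_only`` (default) — only the first occurrence of each
  list item is eligible for runs; later occurrences are labelled
  REPETITION.  ``any_occurrence`` lets every occurrence participate,
  which is what makes overlapping start x end combinations (s + e > n)
  realisable via a repeated boundary item.
* Runs are read as runs of consecutive *response events*: intrusions and
  omission marks break contiguity by default (``runs_broken_by``); kinds
  removed from that set become transparent and are skipped.  An ITEM
  event that is ineligible or does not continue the expected position
  always terminates a run.
* Maximality and ties: the longest qualifying run wins; among equal
  lengths the earliest output index wins.

Annotation labels every event exactly once.  When the same events could
serve both runs (e.g. recall 1 2 3 4 X over n=4), the start-sequence has
priority and the end-sequence is sought among the remaining events, so
START and END always label disjoint events.  A completely correct trial
(recall exactly 1..n, no intrusions, omission marks or repetitions) is
recorded as s=n, e=0 by convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .model import EventKind, Trial

__all__ = [
    "SequencePolicy",
    "SequenceSpan",
    "TrialAnnotation",
    "StartEndTable",
    "find_start_sequence",
    "find_end_sequence",
    "annotate_trial",
    "crosstab_start_end",
    "proportion_complete_correct",
    "sequence_length_summary",
    "start_row_label",
    "end_col_label",
]

Label = Literal["START", "END", "OTHER", "REPETITION", "INTRUSION", "OMISSION"]


@dataclass(frozen=True)
class SequencePolicy:
    """How runs are detected.

    occurrence_rule
        ``"first_occurrence_only"`` (default) or ``"any_occurrence"``.
    runs_broken_by
        Non-ITEM event kinds that interrupt run contiguity.  Kinds not in
        the set are transparent (skipped when scanning).  Default: both
        INTRUSION and OMISSION_MARK break runs.
    """

    occurrence_rule: Literal["first_occurrence_only", "any_occurrence"] = (
        "first_occurrence_only"
    )
    runs_broken_by: frozenset[EventKind] = frozenset(
        {EventKind.INTRUSION, EventKind.OMISSION_MARK}
    )

    @classmethod
    def first(cls) -> "SequencePolicy":
        return cls()

    @classmethod
    def any(cls) -> "SequencePolicy":
        return cls(occurrence_rule="any_occurrence")


@dataclass(frozen=True)
class SequenceSpan:
    """A detected run: its length and the output indices it occupies."""

    length: int
    output_span: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.length != len(self.output_span):
            raise ValueError("length must equal the size of output_span")


EMPTY_SPAN = SequenceSpan(0, ())


@dataclass(frozen=True)
class TrialAnnotation:
    """Per-trial start/end-sequence annotation.

    ``event_labels[j]`` labels recall event with output index ``j+1``;
    ``other_positions`` are the input positions of OTHER-labelled events
    (the items the guess null permutes); ``other_count`` is ``k``.
    """

    trial_id: str
    condition: str
    list_length: int
    start: SequenceSpan
    end: SequenceSpan
    complete_correct: bool
    event_labels: tuple[Label, ...]
    other_positions: tuple[int, ...]

    @property
    def other_count(self) -> int:
        return len(self.other_positions)

    @property
    def outputs_total(self) -> int:
        return len(self.event_labels)


def _eligible_flags(trial: Trial, policy: SequencePolicy) -> list[bool]:
    """Per event: is it an ITEM eligible to join a run?"""
    flags = []
    seen: set[int] = set()
    for e in trial.recall_events:
        if e.kind is not EventKind.ITEM:
            flags.append(False)
            continue
        if policy.occurrence_rule == "any_occurrence":
            flags.append(True)
        else:
            flags.append(e.input_position not in seen)
            seen.add(e.input_position)  # type: ignore[arg-type]
    return flags


def _step(trial: Trial, policy: SequencePolicy, j: int, direction: int) -> int | None:
    """Next scannable event index from j (exclusive) in direction +-1, or
    None if a breaking event or the protocol edge intervenes."""
    events = trial.recall_events
    j += direction
    while 0 <= j < len(events):
        e = events[j]
        if e.kind is EventKind.ITEM:
            return j
        if e.kind in policy.runs_broken_by:
            return None
        j += direction  # transparent kind: skip
    return None


def _scan_runs(
    trial: Trial,
    policy: SequencePolicy,
    anchor_position: int,
    direction: int,
    excluded: frozenset[int] = frozenset(),
) -> SequenceSpan:
    """Find the best run anchored on ``anchor_position`` (item 1 scanned
    forward for starts; item n scanned backward for ends).

    ``excluded`` holds event indices already claimed by another run; they
    terminate scans and cannot anchor one.  Returns the longest run, ties
    broken by earliest output index.
    """
    eligible = _eligible_flags(trial, policy)
    events = trial.recall_events
    best: SequenceSpan = EMPTY_SPAN
    for j, e in enumerate(events):
        if (
            e.kind is not EventKind.ITEM
            or e.input_position != anchor_position
            or not eligible[j]
            or j in excluded
        ):
            continue
        indices = [j]
        expected = anchor_position + direction
        cur = j
        while True:
            nxt = _step(trial, policy, cur, direction)
            if nxt is None or nxt in excluded:
                break
            ne = events[nxt]
            if not eligible[nxt] or ne.input_position != expected:
                break
            indices.append(nxt)
            expected += direction
            cur = nxt
        span = tuple(sorted(events[i].output_index for i in indices))
        if len(span) > best.length or (
            len(span) == best.length and best.length > 0 and span[0] < best.output_span[0]
        ):
            best = SequenceSpan(len(span), span)
    return best


def find_start_sequence(
    trial: Trial, policy: SequencePolicy | None = None
) -> SequenceSpan:
    """Longest run matching input positions 1,2,...,s in forward order,
    located anywhere in the output.  Length 0 iff item 1 is never recalled
    as an eligible occurrence."""
    policy = policy or SequencePolicy()
    return _scan_runs(trial, policy, anchor_position=1, direction=+1)


def find_end_sequence(
    trial: Trial, policy: SequencePolicy | None = None
) -> SequenceSpan:
    """Longest run matching input positions n-e+1,...,n in forward order,
    terminating with item n.  Length 0 iff item n is never recalled as an
    eligible occurrence."""
    policy = policy or SequencePolicy()
    return _scan_runs(trial, policy, anchor_position=trial.n, direction=-1)


def _is_complete_correct(trial: Trial) -> bool:
    events = trial.recall_events
    return len(events) == trial.n and all(
        e.kind is EventKind.ITEM and e.input_position == i + 1
        for i, e in enumerate(events)
    )


def annotate_trial(trial: Trial, policy: SequencePolicy | None = None) -> TrialAnnotation:
    """Label every recall event and extract (s, e, k).

    Labels: START / END for run members, INTRUSION and OMISSION for those
    kinds, REPETITION for later occurrences of an already-recalled item
    outside runs, OTHER for remaining list items.  The end run is sought
    among events not claimed by the start run (start priority), so the
    two label disjoint events.  Completely correct trials are recorded as
    s=n, e=0 with every event labelled START.
    """
    policy = policy or SequencePolicy()
    events = trial.recall_events
    n = trial.n

    if _is_complete_correct(trial):
        span = tuple(e.output_index for e in events)
        return TrialAnnotation(
            trial_id=trial.trial_id,
            condition=trial.condition,
            list_length=n,
            start=SequenceSpan(n, span),
            end=EMPTY_SPAN,
            complete_correct=True,
            event_labels=("START",) * n,
            other_positions=(),
        )

    start = _scan_runs(trial, policy, anchor_position=1, direction=+1)
    start_idx = frozenset(o - 1 for o in start.output_span)
    end = _scan_runs(trial, policy, anchor_position=n, direction=-1, excluded=start_idx)
    end_idx = frozenset(o - 1 for o in end.output_span)

    labels: list[Label] = []
    others: list[int] = []
    seen: set[int] = set()
    for j, e in enumerate(events):
        if j in start_idx:
            labels.append("START")
        elif j in end_idx:
            labels.append("END")
        elif e.kind is EventKind.INTRUSION:
            labels.append("INTRUSION")
        elif e.kind is EventKind.OMISSION_MARK:
            labels.append("OMISSION")
        elif e.input_position in seen:
            labels.append("REPETITION")
        else:
            labels.append("OTHER")
            others.append(e.input_position)  # type: ignore[arg-type]
        if e.kind is EventKind.ITEM:
            seen.add(e.input_position)  # type: ignore[arg-type]
    return TrialAnnotation(
        trial_id=trial.trial_id,
        condition=trial.condition,
        list_length=n,
        start=start,
        end=end,
        complete_correct=False,
        event_labels=tuple(labels),
        other_positions=tuple(others),
    )


def start_row_label(s: int) -> str:
    """Row label in the cross-tabulation layout: 'no start', '1', '12', ..."""
    return "no start" if s == 0 else "".join(str(i) for i in range(1, s + 1))


def end_col_label(e: int, n: int) -> str:
    """Column label: 'No end', 'n', then growing suffixes '(n-1)n', ..."""
    return "No end" if e == 0 else "".join(str(i) for i in range(n - e + 1, n + 1))


@dataclass
class StartEndTable:
    """Trial counts cross-tabulated by (start length, end length).

    ``counts[s, e]`` for s, e in 0..n.  ``n_complete`` counts completely
    correct trials; under the complete-correct convention these sit in
    cell (n, 0), which may also hold non-complete trials whose start run
    spans the whole list (e.g. a full forward recall followed by an
    intrusion).
    """

    n: int
    counts: np.ndarray
    label: str = ""
    n_complete: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (self.n + 1, self.n + 1):
            raise ValueError(f"counts must be shape ({self.n + 1}, {self.n + 1})")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def cell(self, s: int, e: int) -> int:
        return int(self.counts[s, e])

    def to_frame(self) -> pd.DataFrame:
        """Wide layout mirroring the printed table: start rows x end cols."""
        return pd.DataFrame(
            self.counts,
            index=pd.Index([start_row_label(s) for s in range(self.n + 1)], name="start"),
            columns=[end_col_label(e, self.n) for e in range(self.n + 1)],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "n": self.n,
                "label": self.label,
                "n_complete": self.n_complete,
                "counts": self.counts.tolist(),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload

    @classmethod
    def from_cells(
        cls,
        n: int,
        cells: dict[tuple[int, int], int],
        label: str = "",
        n_complete: int | None = None,
    ) -> "StartEndTable":
        counts = np.zeros((n + 1, n + 1), dtype=int)
        for (s, e), c in cells.items():
            counts[s, e] = c
        if n_complete is None:
            n_complete = int(counts[n, 0])
        return cls(n=n, counts=counts, label=label, n_complete=n_complete)


def crosstab_start_end(
    annotations: Iterable[TrialAnnotation], n: int, label: str = ""
) -> StartEndTable:
    """Cross-tabulate annotations of list length ``n`` by (s, e).

    Raises on mixed list lengths: aggregate per length.
    """
    counts = np.zeros((n + 1, n + 1), dtype=int)
    n_complete = 0
    for a in annotations:
        if a.list_length != n:
            raise ValueError(
                f"trial {a.trial_id}: list length {a.list_length} != {n}; "
                "aggregate per list length"
            )
        counts[a.start.length, a.end.length] += 1
        n_complete += a.complete_correct
    return StartEndTable(n=n, counts=counts, label=label, n_complete=n_complete)


def proportion_complete_correct(table: StartEndTable) -> float:
    """Fraction of trials recalled completely correctly ('1 2 ... n')."""
    if table.total == 0:
        raise ValueError("empty table: proportion undefined")
    return table.n_complete / table.total


def sequence_length_summary(
    annotations: Sequence[TrialAnnotation],
    grouping: Sequence[str] = ("condition", "list_length"),
) -> pd.DataFrame:
    """Per-group means of start length, end length and Other count.

    Returns a DataFrame with columns ``mean_start``, ``mean_end``,
    ``mean_other``, ``prop_complete`` and ``n_trials``, grouped by the
    requested annotation fields (any of ``condition``, ``list_length``,
    ``trial_id``).
    """
    if not annotations:
        raise ValueError("no annotations to summarise")
    df = pd.DataFrame(
        {
            "condition": [a.condition for a in annotations],
            "list_length": [a.list_length for a in annotations],
            "trial_id": [a.trial_id for a in annotations],
            "start_len": [a.start.length for a in annotations],
            "end_len": [a.end.length for a in annotations],
            "other_count": [a.other_count for a in annotations],
            "complete": [a.complete_correct for a in annotations],
        }
    )
    out = (
        df.groupby(list(grouping))
        .agg(
            mean_start=("start_len", "mean"),
            mean_end=("end_len", "mean"),
            mean_other=("other_count", "mean"),
            prop_complete=("complete", "mean"),
            n_trials=("trial_id", "size"),
        )
        .reset_index()
    )
    return out
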