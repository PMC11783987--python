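"""Trial data model for immediate-recall protocols.

A :class:`Trial` couples one presented list with the ordered sequence of
responses (recall events) produced for it.  Positions are 1-based
throughout: input serial positions run 1..n over the presented list, and
output positions run 1..m over the recall events, in the temporal order
the responses were produced (spoken/typed order, not written grid
position).

Recall events come in three kinds:

* ``ITEM`` — a response token that matches a presented list item; it
  carries the item's input serial position.
* ``INTRUSION`` — a response token not in the presented list (prior-list
  or extra-list intrusion; the parser does not distinguish the two).
* ``OMISSION_MARK`` — an explicit skip token (e.g. participants typing
  "blank" to signal an omitted position).  The reserved token is
  configurable; the default is ``"blank"``.

Repetitions (the same list item recalled more than once) are represented
losslessly as multiple ``ITEM`` events sharing an input position;
classifying later occurrences as repetitions is the annotator's job, not
the parser's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "EventKind",
    "RecallEvent",
    "Trial",
    "TrialSet",
    "OMISSION_TOKEN",
    "OMISSION_CHAR",
    "parse_letter_trial",
    "render_letter_trial",
    "validate_trial",
]

#: Reserved response token marking an explicit omission in tabular files.
OMISSION_TOKEN = "blank"

#: Single-character omission mark used in letter notation.
OMISSION_CHAR = "-"


class EventKind(Enum):
    ITEM = "ITEM"
    INTRUSION = "INTRUSION"
    OMISSION_MARK = "OMISSION_MARK"


@dataclass(frozen=True)
class RecallEvent:
    """One response in a recall protocol.

    Parameters
    ----------
    output_index
        1-based rank of this response in the recall sequence.
    kind
        Event kind; ``input_position`` is set iff kind is ``ITEM``.
    raw_token
        The literal response token as produced.
    input_position
        1-based serial position of the matching presented item
        (``ITEM`` events only).
    """

    output_index: int
    kind: EventKind
    raw_token: str
    input_position: int | None = None

    def __post_init__(self) -> None:
        if self.kind is EventKind.ITEM and self.input_position is None:
            raise ValueError("ITEM events require an input_position")
        if self.kind is not EventKind.ITEM and self.input_position is not None:
            raise ValueError(f"{self.kind.value} events carry no input_position")


@dataclass(frozen=True)
class Trial:
    """One presented list plus the ordered recall events produced for it."""

    trial_id: str
    condition: str
    presented: tuple[str, ...]
    recall_events: tuple[RecallEvent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "presented", tuple(self.presented))
        object.__setattr__(self, "recall_events", tuple(self.recall_events))
        seen: set[str] = set()
        for tok in self.presented:
            if tok in seen:
                raise ValueError(f"duplicate presented token: {tok!r}")
            seen.add(tok)

    @property
    def list_length(self) -> int:
        return len(self.presented)

    @property
    def n(self) -> int:
        return len(self.presented)

    def item_events(self) -> tuple[RecallEvent, ...]:
        return tuple(e for e in self.recall_events if e.kind is EventKind.ITEM)


@dataclass
class TrialSet:
    """Ordered collection of trials with free-text metadata."""

    trials: list[Trial] = field(default_factory=list)
    metadata: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate trial_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialSet):
            return NotImplemented
        return self.trials == other.trials


def _events_from_tokens(
    presented: Sequence[str],
    tokens: Iterable[str],
    omission_token: str,
) -> tuple[RecallEvent, ...]:
    pos: Mapping[str, int] = {tok: i + 1 for i, tok in enumerate(presented)}
    events = []
    for o, tok in enumerate(tokens, start=1):
        if tok == omission_token:
            events.append(RecallEvent(o, EventKind.OMISSION_MARK, tok))
        elif tok in pos:
            events.append(RecallEvent(o, EventKind.ITEM, tok, pos[tok]))
        else:
            events.append(RecallEvent(o, EventKind.INTRUSION, tok))
    return tuple(events)


def trial_from_tokens(
    trial_id: str,
    condition: str,
    presented: Sequence[str],
    recalled: Sequence[str],
    omission_token: str = OMISSION_TOKEN,
) -> Trial:
    """Build a trial from presented/recalled token sequences.

    Tokens equal to ``omission_token`` become OMISSION_MARK events; tokens
    absent from ``presented`` become INTRUSION events.
    """
    return Trial(
        trial_id=trial_id,
        condition=condition,
        presented=tuple(presented),
        recall_events=_events_from_tokens(presented, recalled, omission_token),
    )


def parse_letter_trial(
    presented_letters: str,
    recalled_letters: str,
    *,
    trial_id: str = "trial1",
    condition: str = "",
    omission_char: str = OMISSION_CHAR,
) -> Trial:
    """Parse the compact letter notation, e.g. list ``"ABCDEFGH"`` with
    recall ``"FGHCABG"``.

    Each character is one token.  Characters absent from
    ``presented_letters`` are intrusions; ``omission_char`` (default
    ``"-"``) marks an explicit skip.  Raises ``ValueError`` on duplicate
    presented characters.
    """
    return trial_from_tokens(
        trial_id,
        condition,
        tuple(presented_letters),
        tuple(recalled_letters),
        omission_token=omission_char,
    )


def render_letter_trial(trial: Trial, *, omission_char: str = OMISSION_CHAR) -> tuple[str, str]:
    """Inverse of :func:`parse_letter_trial`: return (presented, recalled)
    letter strings.  Requires all tokens to be single characters."""
    for tok in trial.presented:
        if len(tok) != 1:
            raise ValueError(f"token {tok!r} is not a single letter")
    out = []
    for e in trial.recall_events:
        if e.kind is EventKind.OMISSION_MARK:
            out.append(omission_char)
        else:
            if len(e.raw_token) != 1:
                raise ValueError(f"token {e.raw_token!r} is not a single letter")
            out.append(e.raw_token)
    return "".join(trial.presented), "".join(out)


def validate_trial(trial: Trial) -> list[str]:
    """Check trial invariants; return human-readable issues (empty if OK).

    Flags, without rejecting: out-of-range input positions, output indices
    not forming the contiguous sequence 1..m, intrusion/item kind
    mismatches against the presented list, and protocols with more
    responses than list items (perseveration — real data, hence a flag).
    """
    issues: list[str] = []
    n = trial.list_length
    presented = set(trial.presented)
    for rank, e in enumerate(trial.recall_events, start=1):
        if e.output_index != rank:
            issues.append(
                f"event {rank}: output_index {e.output_index} != rank {rank} "
                "(output indices must be contiguous 1-based ranks)"
            )
        if e.kind is EventKind.ITEM:
            if not (e.input_position and 1 <= e.input_position <= n):
                issues.append(
                    f"event {rank}: input_position {e.input_position} outside 1..{n}"
                )
            elif trial.presented[e.input_position - 1] != e.raw_token:
                issues.append(
                    f"event {rank}: token {e.raw_token!r} does not match presented "
                    f"item at position {e.input_position}"
                )
        elif e.kind is EventKind.INTRUSION and e.raw_token in presented:
            issues.append(
                f"event {rank}: token {e.raw_token!r} marked INTRUSION but is a list item"
            )
    if len(trial.recall_events) > n:
        issues.append(
            f"{len(trial.recall_events)} recall events exceed list length {n} "
            "(perseveration; accepted but flagged)"
        )
    return issues
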