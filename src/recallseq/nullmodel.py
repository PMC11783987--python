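"""The "start + guess + end" null model for output order.

The model takes each trial's annotation as given — start length s, end
length e, and the identities of the k Other list items — and assumes no
further positional knowledge: start items are output first (in presented
order), end items last (in presented order), and the Other items are
allocated uniformly at random to the k intervening output positions.
The number of output slots equals the number of counted recall events
(s + k + e under the default intrusion policy), which is what makes a
recalled end-sequence on a short protocol land prematurely at early
output positions.

Two estimators of the resulting transposition-error gradient are
provided: a Monte Carlo estimator (replicated uniform permutations of
the Other items) and a closed-form expectation (each Other item with
input position i places probability 1/k on each intervening slot).  The
analytic estimator is the infinite-replication limit of the Monte Carlo
one and is the reference in tests.

Intrusions and repetitions are excluded by default: the estimate
concerns order errors among presented items.  The ``occupy_slot`` policy
instead lets intrusions fill random intervening slots (widening the
middle window) without contributing error counts, for sensitivity
analysis.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .curves import EmptyGradientError, TranspositionTable
from .scoring import TrialAnnotation

__all__ = [
    "GuessNullConfig",
    "NullAssignment",
    "null_assignment",
    "trial_rng",
    "estimated_gradient_mc",
    "estimated_gradient_analytic",
]


@dataclass(frozen=True)
class GuessNullConfig:
    """Null-model settings.

    replications
        Monte Carlo replications per trial (default 1000).
    seed
        Base seed; each trial gets an independent stream derived from
        (seed, trial_id), so results do not depend on trial order.
    intrusion_policy
        ``"exclude"`` (default) or ``"occupy_slot"``.
    estimator
        ``"monte_carlo"`` or ``"analytic"``.
    """

    replications: int = 1000
    seed: int = 0
    intrusion_policy: Literal["exclude", "occupy_slot"] = "exclude"
    estimator: Literal["monte_carlo", "analytic"] = "monte_carlo"

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")


@dataclass(frozen=True)
class NullAssignment:
    """One simulated output order: (input position, output slot) pairs
    for list items, plus the slots used by intrusions (if any occupy)."""

    n: int
    pairs: tuple[tuple[int, int], ...]
    n_slots: int


def _trial_components(
    annotation: TrialAnnotation, intrusion_policy: str
) -> tuple[list[int], list[int], list[int], int]:
    """(start items, other items, end items, number of intrusion slots)."""
    n, s, e = annotation.list_length, annotation.start.length, annotation.end.length
    if annotation.complete_correct:
        return list(range(1, n + 1)), [], [], 0
    start_items = list(range(1, s + 1))
    end_items = list(range(n - e + 1, n + 1))
    others = list(annotation.other_positions)
    n_intr = (
        annotation.event_labels.count("INTRUSION")
        if intrusion_policy == "occupy_slot"
        else 0
    )
    return start_items, others, end_items, n_intr


def trial_rng(seed: int, trial_id: str) -> np.random.Generator:
    """Independent stream per trial, derived from (seed, trial_id)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(trial_id.encode("utf-8"))])
    )


def null_assignment(
    annotation: TrialAnnotation,
    rng: np.random.Generator,
    intrusion_policy: Literal["exclude", "occupy_slot"] = "exclude",
) -> NullAssignment:
    """Draw one output order under the null.

    Start items occupy slots 1..s, end items the last e slots, and the
    Other items (plus intrusions under ``occupy_slot``) a uniform
    permutation of the intervening slots.  Completely correct trials map
    to the identity assignment.
    """
    start_items, others, end_items, n_intr = _trial_components(
        annotation, intrusion_policy
    )
    s, e, k = len(start_items), len(end_items), len(others)
    n_slots = s + k + n_intr + e
    middle = np.asarray(others + [0] * n_intr)
    perm = rng.permutation(len(middle))
    pairs = [(item, slot + 1) for slot, item in enumerate(start_items)]
    for j, item in enumerate(middle[perm]):
        if item > 0:
            pairs.append((int(item), s + 1 + j))
    offset = s + k + n_intr
    pairs.extend((item, offset + j + 1) for j, item in enumerate(end_items))
    pairs.sort(key=lambda p: p[1])
    return NullAssignment(annotation.list_length, tuple(pairs), n_slots)


def _check_annotations(annotations: Sequence[TrialAnnotation]) -> int:
    if not annotations:
        raise ValueError("no annotations")
    lengths = {a.list_length for a in annotations}
    if len(lengths) != 1:
        raise ValueError(f"mixed list lengths {sorted(lengths)}: aggregate per length")
    return lengths.pop()


def estimated_gradient_mc(
    annotations: Sequence[TrialAnnotation],
    config: GuessNullConfig | None = None,
) -> TranspositionTable:
    """Monte Carlo estimate of the error-only transposition gradient.

    Error counts are accumulated over ``replications`` null assignments
    per trial and normalised by the grand total, exactly as the observed
    error gradient is.  Trials with k = 0 are deterministic, so an
    annotation set with no Other items is seed-invariant.
    """
    config = config or GuessNullConfig()
    n = _check_annotations(annotations)
    n_out = max(
        [n]
        + [
            sum(map(len, _trial_components(a, config.intrusion_policy)[:3]))
            + _trial_components(a, config.intrusion_policy)[3]
            for a in annotations
        ]
    )
    counts = np.zeros((n, n_out), dtype=float)
    reps = config.replications
    for a in annotations:
        start_items, others, end_items, n_intr = _trial_components(
            a, config.intrusion_policy
        )
        s, e, k = len(start_items), len(end_items), len(others)
        offset = s + k + n_intr
        # Start items are always in position; end items are deterministic.
        for j, item in enumerate(end_items):
            slot = offset + j + 1
            if slot != item:
                counts[item - 1, slot - 1] += reps
        m = k + n_intr
        if m == 0 or k == 0:
            continue
        rng = trial_rng(config.seed, a.trial_id)
        # ranks[r, j]: slot offset of middle element j in replication r.
        ranks = np.argsort(rng.random((reps, m)), axis=1).argsort(axis=1)
        items = np.asarray(others + [0] * n_intr)
        for j, item in enumerate(items):
            if item == 0:
                continue
            slots = s + 1 + ranks[:, j]
            err = slots != item
            np.add.at(counts[item - 1], slots[err] - 1, 1.0)
    total = counts.sum()
    if total == 0:
        raise EmptyGradientError("no order errors expected under the null")
    return TranspositionTable(n, counts / total, "by_total_errors")


def estimated_gradient_analytic(
    annotations: Sequence[TrialAnnotation],
    intrusion_policy: Literal["exclude", "occupy_slot"] = "exclude",
) -> TranspositionTable:
    """Exact expectation of the error-only gradient under the null.

    Each Other item with input position i contributes probability 1/m to
    each intervening slot (m = number of middle slots); start and end
    contributions are deterministic.  Equals the infinite-replication
    limit of :func:`estimated_gradient_mc`.
    """
    n = _check_annotations(annotations)
    n_out = max(
        [n]
        + [
            sum(map(len, _trial_components(a, intrusion_policy)[:3]))
            + _trial_components(a, intrusion_policy)[3]
            for a in annotations
        ]
    )
    mass = np.zeros((n, n_out), dtype=float)
    for a in annotations:
        start_items, others, end_items, n_intr = _trial_components(
            a, intrusion_policy
        )
        s = len(start_items)
        k = len(others)
        offset = s + k + n_intr
        for j, item in enumerate(end_items):
            slot = offset + j + 1
            if slot != item:
                mass[item - 1, slot - 1] += 1.0
        m = k + n_intr
        for item in others:
            for t in range(m):
                slot = s + 1 + t
                if slot != item:
                    mass[item - 1, slot - 1] += 1.0 / m
    total = mass.sum()
    if total == 0:
        raise EmptyGradientError("no order errors expected under the null")
    return TranspositionTable(n, mass / total, "by_total_errors")
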