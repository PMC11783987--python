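"""Independent brute-force oracles for the scanning scorer and the null.

The window oracle enumerates every contiguous output window and checks
it literally against the run definitions (prefix runs 1..s for starts,
suffix runs n-e+1..n for ends), instead of scanning.  The null oracle
enumerates all k! permutations of the Other items and averages error
counts exactly.  Both are deliberately slow and simple.
"""

from __future__ import annotations

import itertools

import numpy as np

from recallseq.model import EventKind, Trial
from recallseq.scoring import SequencePolicy


def _eligible(trial: Trial, policy: SequencePolicy) -> list[bool]:
    flags, seen = [], set()
    for e in trial.recall_events:
        if e.kind is not EventKind.ITEM:
            flags.append(False)
        elif policy.occurrence_rule == "any_occurrence":
            flags.append(True)
        else:
            flags.append(e.input_position not in seen)
            seen.add(e.input_position)
    return flags


def _window_items(trial, policy, eligible, a, b, excluded):
    """ITEM (position, event index) pairs in window [a, b], or None if the
    window contains a breaking event or an ineligible/excluded ITEM."""
    items = []
    for j in range(a, b + 1):
        e = trial.recall_events[j]
        if e.kind is EventKind.ITEM:
            if not eligible[j] or j in excluded:
                return None
            items.append((e.input_position, j))
        elif e.kind in policy.runs_broken_by:
            return None
        # else transparent: skip
    return items or None


def _best_window(trial, policy, which, excluded=frozenset()):
    """(length, frozenset of ITEM event indices) of the best qualifying
    window; longest wins, then earliest first output index."""
    n, m = trial.n, len(trial.recall_events)
    eligible = _eligible(trial, policy)
    best_len, best_first, best_idx = 0, None, frozenset()
    for a in range(m):
        for b in range(a, m):
            items = _window_items(trial, policy, eligible, a, b, excluded)
            if items is None:
                continue
            positions = [p for p, _ in items]
            L = len(positions)
            if which == "start":
                ok = positions == list(range(1, L + 1))
            else:
                ok = positions == list(range(n - L + 1, n + 1))
            if not ok:
                continue
            first = trial.recall_events[items[0][1]].output_index
            if L > best_len or (L == best_len and best_first is not None and first < best_first):
                best_len, best_first = L, first
                best_idx = frozenset(j for _, j in items)
    return best_len, best_idx


def brute_start_length(trial: Trial, policy: SequencePolicy) -> int:
    return _best_window(trial, policy, "start")[0]


def brute_end_length(trial: Trial, policy: SequencePolicy) -> int:
    return _best_window(trial, policy, "end")[0]


def brute_annotate_lengths(trial: Trial, policy: SequencePolicy) -> tuple[int, int]:
    """(s, e) under the annotation convention: completely correct trials
    are (n, 0); otherwise the start run is chosen first and the end run
    among the remaining events."""
    events = trial.recall_events
    if len(events) == trial.n and all(
        e.kind is EventKind.ITEM and e.input_position == i + 1
        for i, e in enumerate(events)
    ):
        return trial.n, 0
    s, start_idx = _best_window(trial, policy, "start")
    e, _ = _best_window(trial, policy, "end", excluded=start_idx)
    return s, e


def brute_null_expected_errors(n, s, e, others, n_intrusion_slots=0):
    """Expected (input, output) error counts for one annotated trial by
    enumerating every permutation of the middle slots."""
    k = len(others)
    m = k + n_intrusion_slots
    offset = s + m
    n_out = max(n, offset + e)
    counts = np.zeros((n, n_out))
    for j, item in enumerate(range(n - e + 1, n + 1)):
        slot = offset + j + 1
        if slot != item:
            counts[item - 1, slot - 1] += 1.0
    if k == 0:
        return counts
    middle = list(others) + [0] * n_intrusion_slots
    perms = list(itertools.permutations(middle))
    for perm in perms:
        for t, item in enumerate(perm):
            slot = s + 1 + t
            if item > 0 and slot != item:
                counts[item - 1, slot - 1] += 1.0 / len(perms)
    return counts
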