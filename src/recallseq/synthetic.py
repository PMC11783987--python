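"""Synthetic recall-protocol generation.

Two generators are provided:

* :func:`generate_trials` draws protocols from configurable
  distributions over start-sequence length s, end-sequence length e and
  Other-item count k, with optional intrusion / repetition / omission
  noise, for list lengths 2-15.  In *strict mode* every emitted trial is
  guaranteed to annotate back to exactly the sampled (s, e) — candidate
  arrangements that would change the annotation (e.g. an Other item
  s+1 landing immediately after the start run and extending it) are
  rejected and resampled, with acceptance checked by the annotator
  itself.  With strict mode off, such lucky placements are kept, so the
  recovered mean start length exceeds the configured one — the same
  inflation that affects observed sequence lengths in real protocols.

* :func:`generate_from_crosstab` replays a (start length x end length)
  cross-tabulation as concrete trials, cell for cell, such that
  annotating and re-cross-tabulating reproduces the input table exactly.
  Cells with s + e > n are only feasible under the ``any_occurrence``
  policy and are realised by outputting the overlapping boundary items
  twice (e.g. n=6, s=4, e=3 -> "1 2 3 4 4 5 6").

Presented items are the letters A, B, C, ...; intrusion tokens come
from a disjoint lowercase alphabet so parsing is unambiguous.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .model import OMISSION_TOKEN, Trial, TrialSet, trial_from_tokens
from .scoring import SequencePolicy, StartEndTable, annotate_trial

__all__ = ["SyntheticConfig", "generate_trials", "generate_from_crosstab"]

_ITEM_ALPHABET = string.ascii_uppercase  # supports n <= 15 comfortably
_INTRUSION_ALPHABET = string.ascii_lowercase

_MAX_STRICT_RETRIES = 500


def _normalise(dist: Mapping[int, float], name: str) -> dict[int, float]:
    if not dist:
        raise ValueError(f"{name}: empty distribution")
    vals = {int(v): float(p) for v, p in dist.items() if p > 0}
    total = sum(vals.values())
    if total <= 0:
        raise ValueError(f"{name}: probabilities must sum to a positive value")
    return {v: p / total for v, p in sorted(vals.items())}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for protocol simulation.

    ``list_length`` may be an int or a distribution over lengths 2-15.
    ``start_dist`` / ``end_dist`` / ``other_count_dist`` are mappings
    value -> probability (normalised on construction).  A sampled
    (s, e, k) with s + e + k > n is truncated by resampling k first,
    then e, then s, preserving the start length preferentially.  Noise
    rates are per-Other-event probabilities of appending an intrusion,
    a repetition, or an explicit omission mark.
    """

    list_length: int | Mapping[int, float] = 6
    n_trials: int = 100
    p_complete: float = 0.0
    start_dist: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    end_dist: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    other_count_dist: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    intrusion_rate: float = 0.0
    repetition_rate: float = 0.0
    omission_mark_rate: float = 0.0
    strict_mode: bool = False
    seed: int = 0
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_dist", _normalise(self.start_dist, "start_dist"))
        object.__setattr__(self, "end_dist", _normalise(self.end_dist, "end_dist"))
        object.__setattr__(
            self, "other_count_dist", _normalise(self.other_count_dist, "other_count_dist")
        )
        if isinstance(self.list_length, Mapping):
            object.__setattr__(
                self, "list_length", _normalise(self.list_length, "list_length")
            )
            lengths = list(self.list_length)
        else:
            lengths = [int(self.list_length)]
        for n in lengths:
            if not 2 <= n <= 15:
                raise ValueError(f"list_length {n} outside 2..15")
        if not 0.0 <= self.p_complete <= 1.0:
            raise ValueError("p_complete must be in [0, 1]")
        for name in ("intrusion_rate", "repetition_rate", "omission_mark_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if max(self.start_dist) > max(lengths):
            raise ValueError("start_dist support exceeds the largest list length")
        if max(self.end_dist) > max(lengths) - 1:
            raise ValueError(
                "end_dist support must stay below the list length "
                "(a full-length end run is a completely correct trial)"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _draw(dist: Mapping[int, float], rng: np.random.Generator) -> int:
    vals = list(dist)
    return int(vals[rng.choice(len(vals), p=list(dist.values()))])


def _draw_constrained(
    dist: Mapping[int, float], rng: np.random.Generator, max_value: int
) -> int | None:
    feasible = {v: p for v, p in dist.items() if v <= max_value}
    if not feasible:
        return None
    return _draw(_normalise(feasible, "constrained"), rng)


def _sample_sek(
    config: SyntheticConfig, n: int, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Sample (s, e, k); on s + e + k > n resample k, then e, then s."""
    s = _draw_constrained(config.start_dist, rng, n)
    e = _draw(config.end_dist, rng)
    k = _draw(config.other_count_dist, rng)
    if s is None:
        raise ValueError(f"start_dist has no support <= {n}")
    if s + e + k <= n:
        return s, e, k
    k2 = _draw_constrained(config.other_count_dist, rng, n - s - e)
    if k2 is not None:
        return s, e, k2
    min_k = min(config.other_count_dist)
    e2 = _draw_constrained(config.end_dist, rng, n - s - min_k)
    if e2 is not None:
        k2 = _draw_constrained(config.other_count_dist, rng, n - s - e2)
        assert k2 is not None
        return s, e2, k2
    min_e = min(config.end_dist)
    s2 = _draw_constrained(config.start_dist, rng, n - min_e - min_k)
    if s2 is None:
        raise ValueError(
            f"no (s, e, k) combination with s + e + k <= {n} has support"
        )
    e2 = _draw_constrained(config.end_dist, rng, n - s2 - min_k)
    assert e2 is not None
    k2 = _draw_constrained(config.other_count_dist, rng, n - s2 - e2)
    assert k2 is not None
    return s2, e2, k2


def _other_pool(n: int, s: int, e: int, strict: bool) -> list[int]:
    pool = list(range(s + 1, n - e + 1))
    if e == 0 and n in pool:
        pool.remove(n)  # recalling item n would force an end-sequence
    if strict and s == 0 and 1 in pool:
        pool.remove(1)  # recalling item 1 would force a start-sequence
    return pool


def _assemble_tokens(
    n: int,
    s: int,
    e: int,
    others: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
    intrusion_counter: list[int],
) -> list[str]:
    items = _ITEM_ALPHABET[:n]
    start_block = [items[i - 1] for i in range(1, s + 1)]
    end_block = [items[i - 1] for i in range(n - e + 1, n + 1)]
    if len(others) == 0 and 0 < s and 0 < e and s + e == n:
        # start + end blocks back to back would read as a fully correct
        # recall; outputting the end items first realises (s, e) instead.
        return end_block + start_block
    middle: list[str] = []
    for pos in others:
        middle.append(items[pos - 1])
        if config.intrusion_rate and rng.random() < config.intrusion_rate:
            middle.append(
                _INTRUSION_ALPHABET[intrusion_counter[0] % len(_INTRUSION_ALPHABET)]
            )
            intrusion_counter[0] += 1
        if config.repetition_rate and rng.random() < config.repetition_rate:
            emitted = start_block + middle
            repeatable = [tok for tok in emitted if tok in items]
            if repeatable:
                middle.append(repeatable[int(rng.integers(len(repeatable)))])
        if config.omission_mark_rate and rng.random() < config.omission_mark_rate:
            middle.append(OMISSION_TOKEN)
    return start_block + middle + end_block


def generate_trials(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> TrialSet:
    """Generate ``config.n_trials`` protocols.

    Identical (config, seed) always yields an identical TrialSet.  In
    strict mode an explicit error is raised when a sampled (s, e, k) has
    no acceptable arrangement (e.g. k exceeds the eligible Other pool).
    """
    rng = rng or np.random.default_rng(config.seed)
    policy = SequencePolicy()
    trials: list[Trial] = []
    for idx in range(config.n_trials):
        n = (
            _draw(config.list_length, rng)
            if isinstance(config.list_length, Mapping)
            else int(config.list_length)
        )
        items = _ITEM_ALPHABET[:n]
        trial_id = f"syn{idx:05d}"
        if rng.random() < config.p_complete:
            trials.append(
                trial_from_tokens(trial_id, config.condition, tuple(items), tuple(items))
            )
            continue
        s, e, k = _sample_sek(config, n, rng)
        if s == n:  # a full start run is a completely correct recall
            trials.append(
                trial_from_tokens(trial_id, config.condition, tuple(items), tuple(items))
            )
            continue
        pool = _other_pool(n, s, e, config.strict_mode)
        if k > len(pool):
            if config.strict_mode:
                raise ValueError(
                    f"strict_mode unsatisfiable: k={k} Other items requested but only "
                    f"{len(pool)} eligible positions for n={n}, s={s}, e={e}"
                )
            k = len(pool)
        intrusion_counter = [0]
        for attempt in range(_MAX_STRICT_RETRIES):
            others = rng.permutation(pool)[:k]
            tokens = _assemble_tokens(n, s, e, others, config, rng, intrusion_counter)
            trial = trial_from_tokens(trial_id, config.condition, tuple(items), tokens)
            if not config.strict_mode:
                break
            ann = annotate_trial(trial, policy)
            if ann.start.length == s and ann.end.length == e:
                break
        else:
            raise ValueError(
                f"strict_mode: no acceptable arrangement found for n={n}, s={s}, "
                f"e={e}, k={k} after {_MAX_STRICT_RETRIES} attempts"
            )
        trials.append(trial)
    return TrialSet(
        trials=trials,
        metadata={"generator": "generate_trials", "seed": config.seed},
    )


def _cell_positions(n: int, s: int, e: int) -> list[int]:
    """Output order of input positions realising annotation (s, e), k=0."""
    start_block = list(range(1, s + 1))
    end_block = list(range(n - e + 1, n + 1))
    if s == n:
        return start_block
    if s + e < n or s == 0 or e == 0:
        return start_block + end_block
    if s + e == n:
        return end_block + start_block  # back-to-back would be fully correct
    return start_block + end_block  # overlap: boundary items output twice


def generate_from_crosstab(
    table: StartEndTable,
    rng: np.random.Generator | None = None,
    policy: SequencePolicy | None = None,
    condition: str | None = None,
) -> TrialSet:
    """Replay a cross-tabulation as concrete trials, cell for cell.

    Annotating the result under the same ``policy`` and
    re-cross-tabulating reproduces ``table`` exactly.  Overlap cells
    (s + e > n) raise an error naming the cell unless the policy is
    ``any_occurrence``.
    """
    policy = policy or SequencePolicy()
    n = table.n
    condition = condition if condition is not None else table.label
    items = _ITEM_ALPHABET[:n]
    trials: list[Trial] = []
    idx = 0
    for s in range(n + 1):
        for e in range(n + 1):
            count = table.cell(s, e)
            if count == 0:
                continue
            if s == n and e > 0:
                raise ValueError(
                    f"cell (s={s}, e={e}) is infeasible: a full start run is a "
                    "completely correct recall (convention s=n, e=0)"
                )
            if s + e > n and policy.occurrence_rule != "any_occurrence":
                raise ValueError(
                    f"cell (s={s}, e={e}) with s + e > n={n} requires the "
                    "any_occurrence policy (a boundary item output twice)"
                )
            tokens = [items[p - 1] for p in _cell_positions(n, s, e)]
            for _ in range(count):
                trials.append(
                    trial_from_tokens(f"replay{idx:05d}", condition, tuple(items), tokens)
                )
                idx += 1
    return TrialSet(
        trials=trials,
        metadata={"generator": "generate_from_crosstab", "label": table.label},
    )
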