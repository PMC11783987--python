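"""Packaged transcription of the printed six-item ISR cross-tabulation.

Four between-subjects groups of a large typed serial-recall study
(lists of 6 words, ~62 trials per participant) are shipped as a tidy
CSV of trial counts by (start-sequence length, end-sequence length):

* ``Closed ISR`` — closed stimulus set reshuffled every trial;
* ``Open ISR`` — six new words sampled every trial;
* ``Blanks`` — open set, participants typed "blank" to mark omissions;
* ``Open RoO`` — open set with a reconstruction-of-order test.

Two sets of group trial totals circulate for these data: the totals
quoted in the running text (:data:`TEXT_TRIAL_COUNTS`) and the sums of
the printed table cells (:data:`BLOCK_SUMS`), which disagree — the text
apparently rotates three of the four numbers.  All derived proportions
here use the printed block sums, which reproduce the printed
completely-correct proportions (:data:`PRINTED_COMPLETE_PROPORTIONS`).

Cells with start length + end length > 6 (e.g. start "1234" x end
"456") are only realisable when the overlapping boundary item is output
twice, i.e. under the ``any_occurrence`` scoring policy.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .scoring import StartEndTable

__all__ = [
    "LIST_LENGTH",
    "GROUPS",
    "TEXT_TRIAL_COUNTS",
    "BLOCK_SUMS",
    "PRINTED_COMPLETE_PROPORTIONS",
    "load_table1",
    "load_table1_frame",
]

LIST_LENGTH = 6

GROUPS = ("Closed ISR", "Open ISR", "Blanks", "Open RoO")

#: Group trial totals as quoted in the running text.
TEXT_TRIAL_COUNTS = {
    "Open ISR": 6128,
    "Blanks": 6186,
    "Closed ISR": 6198,
    "Open RoO": 5797,
}

#: Sums of the printed table cells (used for all derived proportions).
BLOCK_SUMS = {
    "Closed ISR": 6128,
    "Open ISR": 6186,
    "Blanks": 6198,
    "Open RoO": 5797,
}

#: Completely-correct proportions as printed (cell (6, 0) / block sum).
PRINTED_COMPLETE_PROPORTIONS = {
    "Open RoO": 0.472,
    "Closed ISR": 0.383,
    "Blanks": 0.209,
    "Open ISR": 0.152,
}


def load_table1_frame() -> pd.DataFrame:
    """The tidy transcription: columns group, start_len, end_len, count."""
    with resources.files("recallseq.data").joinpath("table1.csv").open("rb") as fh:
        return pd.read_csv(fh)


def load_table1(group: str | None = None) -> dict[str, StartEndTable] | StartEndTable:
    """Load the cross-tabulation(s) as :class:`StartEndTable` objects.

    With ``group=None`` returns a dict keyed by group name.  The printed
    (6, 0) cell is taken as the completely-correct count.
    """
    df = load_table1_frame()
    tables: dict[str, StartEndTable] = {}
    for g, sub in df.groupby("group", sort=False):
        cells = {
            (int(s), int(e)): int(c)
            for s, e, c in zip(sub["start_len"], sub["end_len"], sub["count"])
        }
        tables[g] = StartEndTable.from_cells(LIST_LENGTH, cells, label=str(g))
    if group is not None:
        return tables[group]
    return tables
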