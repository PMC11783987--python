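"""Start/end-sequence detection, annotation and cross-tabulation."""

import numpy as np
import pytest

from recallseq import (
    SequencePolicy,
    annotate_trial,
    crosstab_start_end,
    find_end_sequence,
    find_start_sequence,
    load_table1,
    parse_letter_trial,
    proportion_complete_correct,
    sequence_length_summary,
    trial_from_tokens,
)
from recallseq.scoring import StartEndTable, end_col_label, start_row_label


class TestFindSequences:
    @pytest.mark.parametrize(
        "recall,start_len,start_span",
        [
            ("FGHCABG", 2, (5, 6)),
            ("HGABCE", 3, (3, 4, 5)),
            ("GFAC", 1, (3,)),
        ],
    )
    def test_start_runs_in_worked_recalls(self, recall, start_len, start_span):
        span = find_start_sequence(parse_letter_trial("ABCDEFGH", recall))
        assert span.length == start_len
        assert span.output_span == start_span

    @pytest.mark.parametrize(
        "recall,end_len,end_span",
        [
            ("FGHCABG", 3, (1, 2, 3)),
            ("HGABCE", 1, (1,)),  # the G after H is backward order
            ("GFAC", 0, ()),  # H never recalled
        ],
    )
    def test_end_runs_in_worked_recalls(self, recall, end_len, end_span):
        span = find_end_sequence(parse_letter_trial("ABCDEFGH", recall))
        assert span.length == end_len
        assert span.output_span == end_span

    def test_empty_recall_has_no_sequences(self):
        t = parse_letter_trial("ABCDEF", "")
        assert find_start_sequence(t).length == 0
        assert find_end_sequence(t).length == 0

    def test_backward_recall_leaves_singleton_runs(self):
        t = parse_letter_trial("ABCDEF", "FEDCBA")
        assert find_end_sequence(t).length == 1  # F alone
        assert find_start_sequence(t).length == 1  # A alone, at the end

    def test_intrusion_breaks_a_run(self):
        t = parse_letter_trial("ABCDEF", "AXBC")
        assert find_start_sequence(t).length == 1

    def test_intrusion_transparent_policy_skips_it(self):
        policy = SequencePolicy(runs_broken_by=frozenset())
        t = parse_letter_trial("ABCDEF", "AXBC")
        assert find_start_sequence(t, policy).length == 3


class TestAnnotateTrial:
    def test_worked_recall_labels_every_event(self):
        a = annotate_trial(parse_letter_trial("ABCDEFGH", "FGHCABG"))
        assert (a.start.length, a.end.length) == (2, 3)
        assert a.event_labels == (
            "END", "END", "END", "OTHER", "START", "START", "REPETITION",
        )
        assert a.other_positions == (3,)
        assert a.other_count == 1
        assert not a.complete_correct

    def test_complete_correct_convention(self):
        a = annotate_trial(parse_letter_trial("ABCDEF", "ABCDEF"))
        assert a.complete_correct
        assert (a.start.length, a.end.length) == (6, 0)
        assert a.other_count == 0
        assert a.event_labels == ("START",) * 6

    def test_explicit_skip_breaks_contiguity(self):
        t = trial_from_tokens("t", "", tuple("ABCDEF"), ("A", "blank", "C", "D", "E", "F"))
        a = annotate_trial(t)
        assert (a.start.length, a.end.length) == (1, 4)
        assert a.other_count == 0
        assert a.event_labels == ("START", "OMISSION", "END", "END", "END", "END")

    def test_start_and_end_label_disjoint_events(self):
        # the same four events form both a full start and a full end run;
        # start priority resolves the conflict
        a = annotate_trial(parse_letter_trial("ABCD", "ABCDX"))
        assert (a.start.length, a.end.length) == (4, 0)
        assert a.event_labels == ("START", "START", "START", "START", "INTRUSION")

    def test_annotation_is_deterministic(self, worked_trials):
        for trial, _, _ in worked_trials:
            assert annotate_trial(trial) == annotate_trial(trial)

    def test_any_occurrence_realises_overlap_via_repeated_item(self, any_policy):
        a = annotate_trial(parse_letter_trial("ABCDEF", "ABCDDEF"), any_policy)
        assert (a.start.length, a.end.length) == (4, 3)

    def test_first_occurrence_treats_second_copy_as_repetition(self, first_policy):
        a = annotate_trial(parse_letter_trial("ABCDEF", "ABCDDEF"), first_policy)
        assert (a.start.length, a.end.length) == (4, 2)
        assert a.event_labels[4] == "REPETITION"


class TestCrosstab:
    @staticmethod
    def _annotations(recalls, n=6):
        items = "ABCDEF"[:n]
        return [
            annotate_trial(parse_letter_trial(items, rec, trial_id=f"t{i}"))
            for i, rec in enumerate(recalls)
        ]

    def test_hand_enumerated_cells(self):
        anns = self._annotations(["ABCDEF", "ABEF", "CDF"])
        table = crosstab_start_end(anns, 6)
        assert table.cell(6, 0) == 1  # complete
        assert table.cell(2, 2) == 1  # 1256
        assert table.cell(0, 1) == 1  # 346: no start run, singleton end
        assert table.total == 3
        assert table.n_complete == 1

    def test_empty_input_gives_all_zero_table(self):
        table = crosstab_start_end([], 6)
        assert table.total == 0

    def test_mixed_list_lengths_rejected(self):
        anns = self._annotations(["ABCDEF"]) + [
            annotate_trial(parse_letter_trial("ABCD", "ABCD", trial_id="x"))
        ]
        with pytest.raises(ValueError, match="list length"):
            crosstab_start_end(anns, 6)

    def test_layout_labels_mirror_printed_table(self):
        frame = StartEndTable.from_cells(6, {(2, 1): 3}).to_frame()
        assert list(frame.index)[:3] == ["no start", "1", "12"]
        assert list(frame.columns)[:3] == ["No end", "6", "56"]
        assert start_row_label(6) == "123456"
        assert end_col_label(5, 6) == "23456"


class TestProportionCompleteCorrect:
    def test_packaged_blocks_reproduce_printed_proportions(self):
        tables = load_table1()
        assert proportion_complete_correct(tables["Open RoO"]) == pytest.approx(
            2739 / 5797
        )
        assert proportion_complete_correct(tables["Closed ISR"]) == pytest.approx(
            2347 / 6128
        )

    def test_single_complete_trial_gives_one(self):
        a = annotate_trial(parse_letter_trial("ABCDEF", "ABCDEF"))
        assert proportion_complete_correct(crosstab_start_end([a], 6)) == 1.0

    def test_empty_table_is_signalled(self):
        with pytest.raises(ValueError, match="empty"):
            proportion_complete_correct(crosstab_start_end([], 6))


class TestSequenceLengthSummary:
    def test_hand_arithmetic(self):
        anns = TestCrosstab._annotations(["ABCDEF", "ABEF", "CDF"])
        out = sequence_length_summary(anns)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["mean_start"] == pytest.approx((6 + 2 + 0) / 3)
        assert row["mean_end"] == pytest.approx((0 + 2 + 1) / 3)
        assert row["n_trials"] == 3
        assert row["prop_complete"] == pytest.approx(1 / 3)

    def test_all_empty_recalls_give_zero_means(self):
        anns = TestCrosstab._annotations(["", ""])
        out = sequence_length_summary(anns)
        assert out.iloc[0]["mean_start"] == 0.0
        assert out.iloc[0]["mean_end"] == 0.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            sequence_length_summary([])
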