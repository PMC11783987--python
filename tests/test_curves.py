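"""Scoring rules, serial-position curves and transposition tables."""

import numpy as np
import pytest

from recallseq import (
    EmptyGradientError,
    SyntheticConfig,
    TrialSet,
    annotate_trial,
    error_gradient,
    generate_trials,
    parse_letter_trial,
    position_curve,
    residual_other_curve,
    score_trial,
    transposition_matrix,
)


def _trial(pres, rec, trial_id="t"):
    return parse_letter_trial(pres, rec, trial_id=trial_id)


def _scored(pres, rec, rule):
    t = _trial(pres, rec)
    return list(score_trial(t, annotate_trial(t), rule))


class TestScoreTrial:
    def test_adjacent_transposition_under_sr_and_fr(self):
        assert _scored("ABCD", "ABDC", "SR") == [1, 1, 0, 0]
        assert _scored("ABCD", "ABDC", "FR") == [1, 1, 1, 1]

    def test_start_end_rule_scores_only_sequence_members(self):
        assert _scored("ABCDEFGH", "FGHCABG", "START_END") == [1, 1, 0, 0, 0, 1, 1, 1]

    def test_one_position_early_scores_zero_under_sr(self):
        # recency items output too early never score as correct
        assert _scored("ABCDEF", "BCDEF", "SR") == [0, 0, 0, 0, 0, 0]

    def test_omission_mark_occupies_a_positional_slot(self):
        t = parse_letter_trial("ABCD", "A-CD")
        assert list(score_trial(t, annotate_trial(t), "SR")) == [1, 0, 1, 1]

    def test_complete_trial_scores_all_correct_under_every_rule(self):
        for rule in ("SR", "FR", "START_END"):
            assert _scored("ABCD", "ABCD", rule) == [1, 1, 1, 1]


class TestPositionCurve:
    def test_single_trial_sr_curve(self):
        ts = TrialSet([_trial("ABCD", "ABDC")])
        curves = position_curve(ts, rule="SR")
        assert list(curves[4].values) == [1, 1, 0, 0]

    def test_excluding_complete_trials_drops_them_from_the_aggregate(self):
        ts = TrialSet([_trial("ABCDEF", "ABCDEF", "c"), _trial("ABCDEF", "BCDEF", "x")])
        curves = position_curve(ts, rule="SR", include_complete=False)
        assert list(curves[6].values) == [0] * 6
        assert curves[6].denominator == 1
        curves_all = position_curve(ts, rule="SR", include_complete=True)
        assert list(curves_all[6].values) == [0.5] * 6

    def test_forced_start_end_pattern_from_generator(self):
        config = SyntheticConfig(
            list_length=6,
            n_trials=40,
            start_dist={2: 1.0},
            end_dist={2: 1.0},
            other_count_dist={0: 1.0},
            strict_mode=True,
            seed=3,
        )
        ts = generate_trials(config)
        curves = position_curve(ts, rule="START_END")
        assert list(curves[6].values) == [1, 1, 0, 0, 1, 1]

    def test_mixed_list_lengths_give_one_curve_per_length(self):
        ts = TrialSet([_trial("ABCD", "ABCD", "a"), _trial("ABCDEF", "ABCDEF", "b")])
        curves = position_curve(ts, rule="SR")
        assert set(curves) == {4, 6}

    def test_recency_alignment_reverses_positions(self):
        ts = TrialSet([_trial("ABCD", "D")])
        curve = position_curve(ts, rule="FR", alignment="recency")[4]
        assert list(curve.values) == [1, 0, 0, 0]

    def test_monotonicity_fr_dominates_sr_and_start_end(self):
        config = SyntheticConfig(
            list_length=6,
            n_trials=300,
            p_complete=0.2,
            start_dist={0: 0.3, 1: 0.3, 2: 0.4},
            end_dist={0: 0.4, 1: 0.3, 2: 0.3},
            other_count_dist={0: 0.4, 1: 0.3, 2: 0.3},
            intrusion_rate=0.15,
            repetition_rate=0.1,
            omission_mark_rate=0.1,
            seed=9,
        )
        for t in generate_trials(config):
            a = annotate_trial(t)
            fr = score_trial(t, a, "FR")
            assert (fr >= score_trial(t, a, "SR")).all()
            assert (fr >= score_trial(t, a, "START_END")).all()

    def test_start_end_correct_count_equals_s_plus_e(self):
        for rec in ("FGHCABG", "HGABCE", "GFAC", "ABCEGH"):
            t = _trial("ABCDEFGH", rec)
            a = annotate_trial(t)
            assert score_trial(t, a, "START_END").sum() == a.start.length + a.end.length


class TestResidualOtherCurve:
    def test_single_worked_trial(self):
        ts = TrialSet([_trial("ABCDEFGH", "FGHCABG")])
        curve = residual_other_curve(ts)[8]
        # item C (input 3) is the only Other item; distance from end = 5
        expected = np.zeros(8)
        expected[5] = 1.0
        assert list(curve.values) == list(expected)
        assert curve.alignment == "recency"

    def test_complete_trial_contributes_zeros(self):
        ts = TrialSet([_trial("ABCDEF", "ABCDEF")])
        assert residual_other_curve(ts)[6].values.sum() == 0.0

    def test_no_recalls_contribute_zeros(self):
        ts = TrialSet([_trial("ABCDEF", "")])
        assert residual_other_curve(ts)[6].values.sum() == 0.0


class TestTranspositionMatrix:
    def test_hand_read_counts(self):
        table = transposition_matrix(TrialSet([_trial("ABCD", "ABDC")]))
        nz = {(i + 1, o + 1): v for (i, o), v in np.ndenumerate(table.counts) if v}
        assert nz == {(1, 1): 1, (2, 2): 1, (3, 4): 1, (4, 3): 1}

    def test_complete_trial_is_all_diagonal(self):
        table = transposition_matrix(TrialSet([_trial("ABCD", "ABCD")]))
        assert (table.counts == np.eye(4)).all()

    def test_partial_recall_counts_observed_outputs_only(self):
        table = transposition_matrix(TrialSet([_trial("ABCD", "DA")]))
        nz = {(i + 1, o + 1): v for (i, o), v in np.ndenumerate(table.counts) if v}
        assert nz == {(4, 1): 1, (1, 2): 1}

    def test_repetitions_count_first_occurrence_only(self):
        table = transposition_matrix(TrialSet([_trial("ABCD", "AAB")]))
        assert table.counts[0].sum() == 1
        assert table.counts[0, 0] == 1

    def test_modal_outputs_on_correct_data_are_the_identity(self):
        ts = TrialSet(
            [_trial("ABCDEF", "ABCDEF", f"t{i}") for i in range(5)]
            + [_trial("ABCDEF", "ABCDFE", "err")]
        )
        table = transposition_matrix(ts)
        assert list(table.counts[:, :6].argmax(axis=1)) == list(range(6))

    def test_mixed_list_lengths_rejected(self):
        ts = TrialSet([_trial("ABCD", "A", "a"), _trial("ABCDEF", "A", "b")])
        with pytest.raises(ValueError, match="mixed"):
            transposition_matrix(ts)


class TestErrorGradient:
    def test_two_errors_share_the_mass_equally(self):
        g = error_gradient(transposition_matrix(TrialSet([_trial("ABCD", "ABDC")])))
        nz = {(i + 1, o + 1): v for (i, o), v in np.ndenumerate(g.counts) if v}
        assert nz == {(3, 4): 0.5, (4, 3): 0.5}

    def test_four_errors_from_two_trials(self):
        ts = TrialSet([_trial("ABCD", "ABDC", "a"), _trial("ABCD", "BACD", "b")])
        g = error_gradient(transposition_matrix(ts))
        nz = {(i + 1, o + 1): v for (i, o), v in np.ndenumerate(g.counts) if v}
        assert nz == {(3, 4): 0.25, (4, 3): 0.25, (1, 2): 0.25, (2, 1): 0.25}

    def test_cells_sum_to_one_whenever_defined(self):
        ts = TrialSet([_trial("ABCDEF", "FCAB")])
        g = error_gradient(transposition_matrix(ts))
        assert g.counts.sum() == pytest.approx(1.0)

    def test_all_diagonal_matrix_signals_empty_gradient(self):
        table = transposition_matrix(TrialSet([_trial("ABCD", "ABCD")]))
        with pytest.raises(EmptyGradientError):
            error_gradient(table)
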