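"""D-score preprocessing/scoring and IPAQ MET scoring."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iatropy.behavior import (ExerciseReport, ScoringError, TrialRecord,
                              apply_error_penalty, assign_group, compute_dscore,
                              compute_met_minutes, filter_trials, score_iat)


def trial(block="compatible", rt=600.0, correct=True, practice=False, iat="affective"):
    return TrialRecord(iat, block, practice, rt, correct)


def block_trials(block, rts, correct=None):
    correct = correct or [True] * len(rts)
    return [trial(block, rt, ok) for rt, ok in zip(rts, correct)]


class TestFilterTrials:
    def test_rt_floor_boundary_keeps_350(self):
        trials = block_trials("compatible", [340, 350, 360]) + block_trials(
            "incompatible", [400, 500])
        res = filter_trials(trials)
        assert [t.rt_ms for t in res.retained if t.block == "compatible"] == [350, 360]
        assert res.participant_ok

    def test_practice_and_missing_dropped(self):
        trials = [trial(practice=True), trial(rt=None), trial(rt=700),
                  trial("incompatible", 600)]
        res = filter_trials(trials)
        assert {t.rt_ms for t in res.retained} == {700, 600}

    def test_error_rate_over_20_percent_excludes(self):
        correct = [False] * 15 + [True] * 57  # 15/72 = 20.8%
        trials = block_trials("compatible", [600.0] * 72, correct) + block_trials(
            "incompatible", [600.0] * 72)
        res = filter_trials(trials)
        assert not res.participant_ok
        assert "20%" in res.reason

    def test_error_rate_at_20_percent_is_kept(self):
        correct = [False] * 14 + [True] * 56  # exactly 0.20
        trials = block_trials("compatible", [600.0] * 70, correct) + block_trials(
            "incompatible", [600.0] * 70)
        assert filter_trials(trials).participant_ok

    def test_all_clean_log_retained_in_full(self):
        trials = block_trials("compatible", [500 + i for i in range(10)]) + block_trials(
            "incompatible", [600 + i for i in range(10)])
        res = filter_trials(trials)
        assert len(res.retained) == 20

    def test_no_formal_trials_flags_participant(self):
        res = filter_trials([trial(practice=True)])
        assert not res.participant_ok
        assert res.reason == "no formal trials"

    def test_idempotent(self):
        trials = block_trials("compatible", [340, 360, 800]) + block_trials(
            "incompatible", [500, 900])
        once = filter_trials(trials).retained
        twice = filter_trials(once).retained
        assert once == twice

    def test_mixed_iat_types_rejected(self):
        with pytest.raises(ValueError, match="single IAT"):
            filter_trials([trial(), trial(iat="instrumental")])


class TestErrorPenalty:
    def test_penalty_is_block_mean_plus_400(self):
        trials = block_trials("compatible", [500, 700, 650], [True, True, False])
        out = apply_error_penalty(trials, "compatible")
        assert [t.rt_ms for t in out] == [500, 700, (500 + 700) / 2 + 400]

    def test_no_errors_identity(self):
        trials = block_trials("compatible", [500, 700])
        assert apply_error_penalty(trials, "compatible") == tuple(trials)

    def test_constant_correct_rts(self):
        trials = block_trials("compatible", [600, 600, 999], [True, True, False])
        assert apply_error_penalty(trials, "compatible")[2].rt_ms == 1000

    def test_no_correct_trials_raises(self):
        trials = block_trials("compatible", [600, 700], [False, False])
        with pytest.raises(ScoringError, match="no correct"):
            apply_error_penalty(trials, "compatible")


class TestDScore:
    def test_hand_computed_example(self):
        compat = block_trials("compatible", [600, 600, 800, 800])
        incompat = block_trials("incompatible", [700, 700, 900, 900])
        pooled_sd = np.std([600, 600, 800, 800, 700, 700, 900, 900], ddof=1)
        assert compute_dscore(compat, incompat) == pytest.approx(100 / pooled_sd)

    def test_identical_blocks_give_zero(self):
        rts = [500, 600, 700.0]
        assert compute_dscore(block_trials("compatible", rts),
                              block_trials("incompatible", rts)) == 0.0

    @given(scale=st.floats(0.1, 10), shift=st.floats(0, 500))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, scale, shift):
        """Scaling all RTs leaves D unchanged; a common shift also cancels."""
        compat = [520.0, 610, 680, 850]
        incompat = [590.0, 700, 760, 930]
        d0 = compute_dscore(block_trials("compatible", compat),
                            block_trials("incompatible", incompat))
        d1 = compute_dscore(
            block_trials("compatible", [scale * v + shift for v in compat]),
            block_trials("incompatible", [scale * v + shift for v in incompat]))
        assert d1 == pytest.approx(d0, rel=1e-9)

    def test_two_sample_sd_mode(self):
        compat = block_trials("compatible", [600, 600, 800, 800])
        incompat = block_trials("incompatible", [700, 700, 900, 900])
        va = np.var([600, 600, 800, 800], ddof=1)
        vb = np.var([700, 700, 900, 900], ddof=1)
        pooled = np.sqrt((3 * va + 3 * vb) / 6)
        assert compute_dscore(compat, incompat, sd_mode="two_sample") == pytest.approx(
            100 / pooled)

    def test_zero_sd_raises(self):
        with pytest.raises(ScoringError, match="SD"):
            compute_dscore(block_trials("compatible", [600, 600]),
                           block_trials("incompatible", [600, 600]))

    def test_score_iat_full_chain_with_penalty(self):
        compat = block_trials("compatible", [500, 700, 600, 600, 650],
                              [True, True, True, True, False])  # 20% errors: kept
        incompat = block_trials("incompatible", [700, 900])
        res = score_iat(compat + incompat)
        assert not res.excluded_participant
        # penalty: mean correct compatible (600) + 400 = 1000
        sd = np.std([500, 700, 600, 600, 700, 900], ddof=1)
        expected = (800 - (500 + 700 + 600 + 600 + 1000) / 5) / sd
        assert res.d_score == pytest.approx(expected)
        assert res.n_trials_used == 7

    def test_score_iat_excludes_high_error_participant(self):
        compat = block_trials("compatible", [600.0] * 10, [False] * 3 + [True] * 7)
        incompat = block_trials("incompatible", [700.0] * 10)
        res = score_iat(compat + incompat)
        assert res.excluded_participant
        assert res.d_score is None


class TestExerciseScoring:
    def test_met_components(self):
        met = compute_met_minutes(ExerciseReport(walking_days=3, walking_min=30,
                                                 vigorous_days=3, vigorous_min=40))
        assert met["walking"] == pytest.approx(297.0)  # 3.3 * 30 * 3
        assert met["vigorous"] == pytest.approx(960.0)  # 8 * 40 * 3
        assert met["mvpa_total"] == pytest.approx(960.0)

    def test_walking_excluded_from_mvpa(self):
        report = ExerciseReport(walking_days=6, walking_min=30)
        met = compute_met_minutes(report)
        assert met["walking"] == pytest.approx(594.0)
        assert met["mvpa_total"] == 0.0
        assert assign_group(report).label == "non_exercise"

    def test_all_zero_report(self):
        met = compute_met_minutes(ExerciseReport())
        assert all(v == 0 for v in met.values())

    def test_any_mvpa_is_exercise(self):
        label = assign_group(ExerciseReport(moderate_days=1, moderate_min=10))
        assert label.label == "exercise"
        assert label.mvpa_met_min_week == pytest.approx(40.0)

    @given(days=st.integers(0, 7), minutes=st.floats(0, 300))
    @settings(max_examples=25, deadline=None)
    def test_met_linear_in_minutes(self, days, minutes):
        met1 = compute_met_minutes(ExerciseReport(moderate_days=days, moderate_min=minutes))
        met2 = compute_met_minutes(ExerciseReport(moderate_days=days, moderate_min=2 * minutes))
        assert met2["moderate"] == pytest.approx(2 * met1["moderate"])

    def test_invalid_report_rejected(self):
        with pytest.raises(ValueError):
            ExerciseReport(walking_days=8)
        with pytest.raises(ValueError):
            ExerciseReport(moderate_min=-1)
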