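"""Synthetic cohort generator: structure, determinism, planted effect."""

from __future__ import annotations

import numpy as np
import pytest

from iatropy.behavior import assign_group, score_iat
from iatropy.entropy import EntropyConfig, batch_envelope
from iatropy.montage import CHANNELS, CONDITIONS, IAT_TYPES
from iatropy.preprocessing import preprocess_epochs, reject_epochs
from iatropy.synthetic import (CohortSpec, ConfigurationError, ParticipantProfile,
                               generate_cohort, generate_eeg_epochs,
                               generate_exercise_report, generate_trial_log)
from iatropy.rng import substream

from .conftest import ANALYSIS_RATE_HZ, cohort_features, scaled_spec


def profile(seed=0, group="exercise", d=1.0, **kw):
    spec = scaled_spec(seed, effect_size_d=d, **kw)
    return ParticipantProfile("sub-001", group, trait=0.0, spec=spec)


class TestCohortStructure:
    def test_group_counts_and_order(self):
        cohort = generate_cohort(scaled_spec(1, trials=2, n_exercise=5, n_nonexercise=3))
        assert len(cohort) == 8
        assert sum(r.group_label == "exercise" for r in cohort) == 5

    def test_default_split_sizes(self):
        spec = CohortSpec()
        assert spec.n_exercise == 33 and spec.n_nonexercise == 23
        assert spec.n_trials_per_block == 72 and spec.n_practice_per_block == 24

    def test_condition_keys_are_canonical(self, tiny_cohort):
        for rec in tiny_cohort:
            assert set(rec.epoch_sets) == set(CONDITIONS)

    def test_labels_match_met_rule_for_all_participants(self, tiny_cohort):
        for rec in tiny_cohort:
            assert assign_group(rec.exercise_report).label == rec.group_label

    def test_invalid_spec_names_field(self):
        with pytest.raises(ConfigurationError, match="n_exercise"):
            CohortSpec(n_exercise=0).validate()
        with pytest.raises(ConfigurationError, match="effect_size_d"):
            CohortSpec(effect_size_d=-1).validate()
        with pytest.raises(ConfigurationError, match="effect_conditions"):
            CohortSpec(effect_conditions=("nonsense",)).validate()


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = generate_cohort(scaled_spec(3, trials=2, n_exercise=2, n_nonexercise=2))
        b = generate_cohort(scaled_spec(3, trials=2, n_exercise=2, n_nonexercise=2))
        for ra, rb in zip(a, b):
            assert ra.trial_log == rb.trial_log
            assert ra.exercise_report == rb.exercise_report
            for c in CONDITIONS:
                np.testing.assert_array_equal(ra.epoch_sets[c].data, rb.epoch_sets[c].data)

    def test_adding_participants_does_not_perturb_existing(self):
        small = generate_cohort(scaled_spec(3, trials=2, n_exercise=2, n_nonexercise=2))
        big = generate_cohort(scaled_spec(3, trials=2, n_exercise=4, n_nonexercise=2))
        np.testing.assert_array_equal(
            small[0].epoch_sets["affective_compatible"].data,
            big[0].epoch_sets["affective_compatible"].data)


class TestEpochs:
    def test_epoch_window_and_channels(self):
        rng = substream(0, "t")
        eset = generate_eeg_epochs(profile(), "affective_compatible", rng, 3)
        assert eset.data.shape == (3, len(CHANNELS), int(1.5 * 200))
        assert eset.t_start_ms == -500.0

    def test_unknown_condition_rejected(self):
        with pytest.raises(ConfigurationError, match="condition"):
            generate_eeg_epochs(profile(), "resting", substream(0, "t"), 1)

    def test_artifact_free_within_100_uv(self, tiny_cohort):
        for rec in tiny_cohort:
            for eset in rec.epoch_sets.values():
                assert np.abs(eset.data).max() <= 100.0

    def test_artifact_injector_trips_rejection(self):
        p = profile(artifact_rate=1.0)
        eset = generate_eeg_epochs(p, "affective_compatible", substream(0, "a"), 4)
        with pytest.raises(Exception):
            reject_epochs(eset)

    def test_zero_burstiness_maximizes_envelope_entropy(self):
        """Envelope entropy decreases monotonically with modulation depth."""
        cfgs = [profile(burst_base=b, d=0.0, burst_sd=0.0) for b in (0.06, 0.45, 0.85)]
        means = []
        for p in cfgs:
            eset = generate_eeg_epochs(p, "affective_compatible", substream(7, "b"), 12)
            kept, _ = preprocess_epochs(eset, ANALYSIS_RATE_HZ)
            h = batch_envelope(kept.data.reshape(-1, kept.n_samples))
            means.append(h.mean())
        assert means[0] > means[1] > means[2]


class TestTrialLogs:
    def test_block_structure_matches_task_design(self):
        spec = CohortSpec(seed=5)
        p = ParticipantProfile("sub-001", "exercise", 0.0, spec)
        log = generate_trial_log(p, substream(5, "trials"))
        assert len(log) == 2 * 2 * (24 + 72)
        for iat in IAT_TYPES:
            for block in ("compatible", "incompatible"):
                sub = [t for t in log if t.iat_type == iat and t.block == block]
                assert len(sub) == 96
                assert sum(not t.practice for t in sub) == 72

    def test_clean_config_loses_no_trials_to_filters(self):
        p = profile(error_rate=0.0, fast_rate=0.0, missing_rate=0.0)
        log = generate_trial_log(p, substream(1, "trials"))
        from iatropy.behavior import filter_trials

        res = filter_trials([t for t in log if t.iat_type == "affective"])
        assert res.participant_ok
        assert len(res.retained) == 2 * p.spec.n_trials_per_block

    def test_null_shift_gives_zero_mean_dscore(self):
        """With no compatible/incompatible RT shift, mean D over many
        simulated participants is indistinguishable from zero."""
        spec = CohortSpec(rt_incompat_shift_ms=0.0, seed=9)
        ds = []
        for i in range(500):
            p = ParticipantProfile(f"sub-{i}", "exercise", 0.0, spec)
            log = generate_trial_log(p, substream(9, f"sub-{i}", "trials"))
            res = score_iat([t for t in log if t.iat_type == "affective"])
            if res.d_score is not None:
                ds.append(res.d_score)
        assert abs(np.mean(ds)) < 0.05

    def test_positive_shift_gives_positive_dscore(self):
        spec = CohortSpec(seed=9)  # default +80 ms incompatible shift
        ds = []
        for i in range(100):
            p = ParticipantProfile(f"sub-{i}", "exercise", 0.0, spec)
            log = generate_trial_log(p, substream(10, f"sub-{i}", "trials"))
            res = score_iat([t for t in log if t.iat_type == "affective"])
            ds.append(res.d_score)
        assert np.mean(ds) > 0.3


class TestExerciseReports:
    def test_non_exerciser_has_zero_mvpa(self):
        for s in range(20):
            rep = generate_exercise_report("non_exercise", substream(s, "ipaq"))
            assert rep.moderate_min == 0 and rep.vigorous_min == 0

    def test_exerciser_has_positive_mvpa(self):
        for s in range(20):
            rep = generate_exercise_report("exercise", substream(s, "ipaq"))
            assert assign_group(rep).label == "exercise"

    def test_unknown_group_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_exercise_report("couch", substream(0, "x"))


def regional_envelope_d(seed: int, d: float, trials: int = 4) -> float:
    """Realized standardized group difference of frontal envelope entropy in
    the affective-incompatible condition for one cohort."""
    cohort = generate_cohort(scaled_spec(seed, trials=trials, effect_size_d=d))
    table = cohort_features(cohort, metrics=("envelope",),
                            conditions=("affective_incompatible",))
    sub = table[table.region == "frontal"].set_index("participant_id")["value"]
    labels = {r.participant_id: r.group_label for r in cohort}
    a = sub[[p for p in sub.index if labels[p] == "exercise"]].to_numpy()
    b = sub[[p for p in sub.index if labels[p] == "non_exercise"]].to_numpy()
    pooled = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                     / (a.size + b.size - 2))
    return float((a.mean() - b.mean()) / pooled)


class TestPlantedEffect:
    def test_effect_size_calibration(self):
        """Monte-Carlo: realized feature-level d tracks the nominal value."""
        ds = [regional_envelope_d(100 + s, 1.5) for s in range(25)]
        assert np.mean(ds) == pytest.approx(1.5, abs=0.3)

    def test_null_effect_centered_at_zero(self):
        ds = [regional_envelope_d(200 + s, 0.0, trials=2) for s in range(15)]
        assert abs(np.mean(ds)) < 0.25

    def test_effect_monotone_in_d(self):
        grid = []
        for d in (0.0, 0.75, 1.5):
            grid.append(np.mean([regional_envelope_d(300 + s, d, trials=2)
                                 for s in range(12)]))
        assert grid[0] < grid[1] < grid[2]
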