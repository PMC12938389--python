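"""Synthetic cohorts: EEG epochs, IAT trial logs and exercise recalls.

The generator emulates the statistical structure the downstream analysis
assumes, not biophysically realistic EEG.  Each epoch is a sum of
band-limited oscillations (theta/alpha/beta carriers) under a common
low-frequency random amplitude modulation, plus 1/f-like background noise
and a small stimulus-locked potential.  The modulation depth ("burstiness"
beta in [0, 1)) controls the variability of the Hilbert amplitude envelope:
beta = 0 gives a near-constant envelope (envelope entropy at its maximum
for the epoch length), larger beta gives burstier amplitude dynamics and
lower envelope entropy.

The planted group difference lowers burstiness for the exercise group —
i.e. raises their expected envelope entropy — only in the configured effect
conditions x regions.  ``effect_size_d`` is the standardized between-group
difference of the per-participant burstiness parameter; because regional
envelope entropy is (locally) a monotone, nearly linear readout of
burstiness and epoch/electrode averaging suppresses measurement noise, the
realized standardized difference of the regional envelope-entropy feature
tracks ``effect_size_d`` (verified by Monte-Carlo calibration in the test
suite).

All randomness flows from ``CohortSpec.seed`` through named substreams per
participant x stage x condition, so cohorts are reproducible and adding
participants does not perturb existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .behavior import ExerciseReport, TrialRecord, assign_group
from .montage import BLOCKS, CHANNELS, CONDITION_PARTS, CONDITIONS, IAT_TYPES, REGIONS, region_of
from .preprocessing import EPOCH_TMAX_MS, EPOCH_TMIN_MS, EpochSet
from .rng import substream


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSpec:
    """Study-design and signal-model parameters for one synthetic cohort."""

    n_exercise: int = 33
    n_nonexercise: int = 23
    effect_size_d: float = 1.0
    effect_conditions: tuple[str, ...] = ("affective_incompatible",)
    effect_regions: tuple[str, ...] = ("frontal", "fronto_central", "central")
    n_trials_per_block: int = 72
    n_practice_per_block: int = 24
    sampling_rate_hz: float = 1000.0
    seed: int = 0
    # signal model
    burst_base: float = 0.45
    burst_sd: float = 0.10
    carrier_freqs_hz: tuple[float, ...] = (5.0, 10.0, 22.0)
    carrier_amps_uv: tuple[float, ...] = (6.0, 10.0, 5.0)
    noise_rms_uv: float = 3.0
    erp_amp_uv: float = 4.0
    artifact_rate: float = 0.0  # per-epoch probability of a >100 uV spike
    # behavior model
    rt_mu_ms: float = 550.0
    rt_incompat_shift_ms: float = 80.0
    rt_sigma_ms: float = 80.0
    rt_tau_ms: float = 120.0
    error_rate: float = 0.08
    fast_rate: float = 0.02
    missing_rate: float = 0.01

    def validate(self) -> None:
        if self.n_exercise < 1:
            raise ConfigurationError("n_exercise must be >= 1")
        if self.n_nonexercise < 1:
            raise ConfigurationError("n_nonexercise must be >= 1")
        if self.effect_size_d < 0:
            raise ConfigurationError("effect_size_d must be >= 0")
        if self.sampling_rate_hz <= 80:
            raise ConfigurationError("sampling_rate_hz must exceed 80")
        if not set(self.effect_conditions) <= set(CONDITIONS):
            raise ConfigurationError("effect_conditions contains an unknown condition label")
        if not set(self.effect_regions) <= set(REGIONS):
            raise ConfigurationError("effect_regions contains an unknown region label")
        if self.n_trials_per_block < 1:
            raise ConfigurationError("n_trials_per_block must be >= 1")
        for rate_field in ("error_rate", "fast_rate", "missing_rate", "artifact_rate"):
            v = getattr(self, rate_field)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{rate_field} must be in [0, 1]")
        if not 0 < self.burst_base < 1:
            raise ConfigurationError("burst_base must be in (0, 1)")


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    group_label: str
    trait: float  # latent burstiness trait, N(0,1)
    spec: CohortSpec


@dataclass
class ParticipantRecord:
    participant_id: str
    group_label: str
    epoch_sets: dict[str, EpochSet]
    trial_log: list[TrialRecord]
    exercise_report: ExerciseReport


def _spectral_noise(
    rng: np.random.Generator, n: int, fs: float, f_lo: float, f_hi: float,
    exponent: float = 0.0, size: int | None = None,
) -> np.ndarray:
    """Unit-SD Gaussian noise with power confined to [f_lo, f_hi] and a
    1/f^exponent power slope, via random-phase spectral synthesis.

    With ``size`` returns a (size, n) batch of independent realizations.
    """
    b = 1 if size is None else size
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    band = (freqs >= f_lo) & (freqs <= min(f_hi, fs / 2))
    amp = np.zeros_like(freqs)
    if exponent:
        amp[band] = freqs[band] ** (-exponent / 2.0)
    else:
        amp[band] = 1.0
    phases = rng.uniform(0.0, 2.0 * np.pi, (b, freqs.size))
    spec = amp[None, :] * np.exp(1j * phases)
    x = np.fft.irfft(spec, n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    x /= sd
    return x[0] if size is None else x


def burstiness(profile: ParticipantProfile, condition: str, channel: str,
               jitter: float = 0.0) -> float:
    """Modulation depth for one channel, with the planted effect applied."""
    spec = profile.spec
    beta = spec.burst_base + spec.burst_sd * (profile.trait + 0.2 * jitter)
    if (
        profile.group_label == "exercise"
        and condition in spec.effect_conditions
        and region_of(channel) in spec.effect_regions
    ):
        beta -= spec.effect_size_d * spec.burst_sd  # exercisers: higher envelope entropy
    return float(np.clip(beta, 0.05, 0.90))


def generate_eeg_epochs(
    profile: ParticipantProfile,
    condition: str,
    rng: np.random.Generator,
    n_epochs: int,
) -> EpochSet:
    """Generate stimulus-locked epochs (-500..1000 ms) for one condition."""
    if condition not in CONDITIONS:
        raise ConfigurationError(f"unknown condition label {condition!r}")
    spec = profile.spec
    fs = spec.sampling_rate_hz
    n = int(round((EPOCH_TMAX_MS - EPOCH_TMIN_MS) * fs / 1000.0))
    t = EPOCH_TMIN_MS / 1000.0 + np.arange(n) / fs
    erp = spec.erp_amp_uv * np.exp(-0.5 * ((t - 0.30) / 0.05) ** 2)
    region_jitter = {r: rng.normal() for r in REGIONS}
    n_ch = len(CHANNELS)
    betas = np.array([
        burstiness(profile, condition, ch, region_jitter[region_of(ch)]) for ch in CHANNELS
    ])
    b = n_epochs * n_ch  # one independent realization per epoch x channel
    mod = _spectral_noise(rng, n, fs, 0.3, 3.0, size=b)
    env = np.clip(1.0 + np.tile(betas, n_epochs)[:, None] * mod, 0.05, 2.8)
    osc = np.zeros((b, n))
    for f_c, a_c in zip(spec.carrier_freqs_hz, spec.carrier_amps_uv):
        phases = rng.uniform(0.0, 2.0 * np.pi, (b, 1))
        osc += a_c * np.cos(2.0 * np.pi * f_c * t[None, :] + phases)
    noise = spec.noise_rms_uv * _spectral_noise(rng, n, fs, 3.0, 45.0, exponent=1.0, size=b)
    data = (env * osc + noise + erp[None, :]).reshape(n_epochs, n_ch, n)
    if spec.artifact_rate:
        for e in range(n_epochs):
            if rng.random() < spec.artifact_rate:
                data[e, rng.integers(0, n_ch), rng.integers(0, n)] += (
                    rng.choice([-1.0, 1.0]) * 150.0
                )
    return EpochSet(
        data, CHANNELS, fs, condition,
        t_start_ms=EPOCH_TMIN_MS, participant_id=profile.participant_id,
    )


def generate_trial_log(profile: ParticipantProfile, rng: np.random.Generator) -> list[TrialRecord]:
    """One compatible + one incompatible block per IAT type.

    RTs are ex-Gaussian with a configurable incompatible-block mean shift;
    error, fast-response (<350 ms) and missing-response rates are
    configurable.
    """
    spec = profile.spec
    trials: list[TrialRecord] = []
    for iat in IAT_TYPES:
        for block in BLOCKS:
            mu = spec.rt_mu_ms + (spec.rt_incompat_shift_ms if block == "incompatible" else 0.0)
            for practice, count in ((True, spec.n_practice_per_block),
                                    (False, spec.n_trials_per_block)):
                for _ in range(count):
                    rt = mu + rng.normal(0.0, spec.rt_sigma_ms) + rng.exponential(spec.rt_tau_ms)
                    rt = max(rt, 360.0)
                    if rng.random() < spec.fast_rate:
                        rt = rng.uniform(200.0, 349.0)
                    rt_val: float | None = float(rt)
                    if rng.random() < spec.missing_rate:
                        rt_val = None
                    correct = rng.random() >= spec.error_rate
                    trials.append(TrialRecord(iat, block, practice, rt_val, correct))
    return trials


def generate_exercise_report(group_label: str, rng: np.random.Generator) -> ExerciseReport:
    """Non-exercisers: zero moderate and vigorous activity (walking allowed)."""
    walking_days = int(rng.integers(0, 6))
    walking_min = 0.0 if walking_days == 0 else float(rng.integers(10, 41))
    if group_label == "non_exercise":
        return ExerciseReport(walking_days, walking_min, 0.0, 0.0, 0.0, 0.0)
    if group_label != "exercise":
        raise ConfigurationError(f"unknown group label {group_label!r}")
    moderate_days = int(rng.integers(1, 6))
    moderate_min = float(rng.integers(20, 61))
    vigorous_days = int(rng.integers(0, 4))
    vigorous_min = 0.0 if vigorous_days == 0 else float(rng.integers(20, 46))
    return ExerciseReport(walking_days, walking_min,
                          moderate_days, moderate_min, vigorous_days, vigorous_min)


def _epoch_counts(trials: Sequence[TrialRecord]) -> dict[str, int]:
    counts = {}
    for condition, (iat, block) in CONDITION_PARTS.items():
        counts[condition] = sum(
            1 for tr in trials
            if tr.iat_type == iat and tr.block == block and not tr.practice and tr.correct
        )
    return counts


def generate_participant(spec: CohortSpec, participant_id: str, group_label: str) -> ParticipantRecord:
    profile = ParticipantProfile(
        participant_id, group_label,
        trait=float(substream(spec.seed, participant_id, "trait").normal()),
        spec=spec,
    )
    report = generate_exercise_report(group_label, substream(spec.seed, participant_id, "ipaq"))
    assert assign_group(report).label == group_label  # generator self-consistency
    trial_log = generate_trial_log(profile, substream(spec.seed, participant_id, "trials"))
    epoch_sets = {
        condition: generate_eeg_epochs(
            profile, condition, substream(spec.seed, participant_id, "eeg", condition), n_ep,
        )
        for condition, n_ep in _epoch_counts(trial_log).items()
    }
    return ParticipantRecord(participant_id, group_label, epoch_sets, trial_log, report)


def generate_cohort(spec: CohortSpec) -> list[ParticipantRecord]:
    """Generate the full cohort (exercise participants first)."""
    spec.validate()
    records = []
    k = 0
    for group, count in (("exercise", spec.n_exercise), ("non_exercise", spec.n_nonexercise)):
        for _ in range(count):
            k += 1
            records.append(generate_participant(spec, f"sub-{k:03d}", group))
    return records


def cohort_labels(cohort: Sequence[ParticipantRecord]) -> dict[str, str]:
    return {rec.participant_id: rec.group_label for rec in cohort}


def cohort_epoch_sets(cohort: Sequence[ParticipantRecord]) -> list[EpochSet]:
    return [eset for rec in cohort for eset in rec.epoch_sets.values()]
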