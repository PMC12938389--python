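"""Epoch-form EEG preprocessing.

Continuous-data path (real recordings): re-reference (pass-through hook) ->
downsample -> 3-40 Hz zero-phase FIR band-pass -> epoch extraction
(-500..1000 ms around stimulus onset, correct formal trials only) ->
baseline correction (-200..0 ms) -> amplitude rejection (any sample
|x| > 100 uV drops the epoch).

Epoch-form path (synthetic cohorts are generated directly as clean,
band-limited epochs): resample -> baseline -> reject.

Filter design: odd-length windowed-sinc FIR (Hamming), -6 dB at the band
edges, applied once with group-delay compensation (linear phase, so the
compensated output is zero-phase).  The default transition width of 3 Hz
around the 3 Hz edge puts >40 dB of attenuation at 1.5 Hz; the Hamming
window's ~53 dB stop-band covers the 53 Hz requirement at the upper edge.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

log = logging.getLogger(__name__)

EPOCH_TMIN_MS = -500.0
EPOCH_TMAX_MS = 1000.0
BASELINE_MS = (-200.0, 0.0)
REJECT_UV = 100.0


class PreprocessingError(ValueError):
    pass


class AllEpochsRejected(PreprocessingError):
    """Every epoch of a participant-condition exceeded the amplitude bound."""


@dataclass
class EpochSet:
    """Stimulus-locked epochs for one participant x condition.

    data: (n_epochs, n_channels, n_samples) in microvolts.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    sampling_rate_hz: float
    condition: str
    t_start_ms: float = EPOCH_TMIN_MS
    baseline_window_ms: tuple[float, float] = BASELINE_MS
    participant_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length must match data")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t_start_ms + 1000.0 * np.arange(self.n_samples) / self.sampling_rate_hz

    def sample_of_ms(self, t_ms: float) -> int:
        return int(round((t_ms - self.t_start_ms) * self.sampling_rate_hz / 1000.0))


def design_bandpass(
    rate: float,
    band: tuple[float, float] = (3.0, 40.0),
    transition_hz: float = 3.0,
) -> np.ndarray:
    """Windowed-sinc FIR band-pass with -6 dB points at ``band``."""
    lo, hi = band
    if not 0 < lo < hi < rate / 2:
        raise ValueError("band edges must satisfy 0 < lo < hi < Nyquist")
    numtaps = int(math.ceil(3.3 * rate / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay, type-I FIR
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=rate)


def bandpass_filter(
    continuous: np.ndarray,
    rate: float,
    band: tuple[float, float] = (3.0, 40.0),
    transition_hz: float = 3.0,
) -> np.ndarray:
    """Zero-phase band-pass of (channels, samples) continuous data."""
    x = np.atleast_2d(np.asarray(continuous, dtype=np.float64))
    if rate <= 80:
        raise PreprocessingError("sampling rate must exceed 80 Hz for a 3-40 Hz band")
    taps = design_bandpass(rate, band, transition_hz)
    if x.shape[1] < 3 * taps.size:
        raise PreprocessingError(
            f"signal length {x.shape[1]} shorter than 3x filter length ({3 * taps.size})"
        )
    pad = taps.size
    padded = np.pad(x, ((0, 0), (pad, pad)), mode="reflect")
    out = signal.fftconvolve(padded, taps[None, :], mode="same", axes=1)
    out = out[:, pad:-pad]
    return out if np.ndim(continuous) == 2 else out[0]


def downsample(continuous: np.ndarray, from_rate: float, to_rate: float = 500.0) -> np.ndarray:
    """Anti-alias-protected resampling of the last axis."""
    if to_rate > from_rate:
        raise PreprocessingError("to_rate must not exceed from_rate")
    if to_rate == from_rate:
        return np.asarray(continuous, dtype=np.float64)
    frac = Fraction(to_rate / from_rate).limit_denominator(1000)
    return signal.resample_poly(np.asarray(continuous, dtype=np.float64),
                                frac.numerator, frac.denominator, axis=-1)


def extract_epochs(
    continuous: np.ndarray,
    events: Sequence[int],
    rate: float,
    channel_names: Sequence[str],
    condition: str,
    correct_mask: Sequence[bool] | None = None,
    tmin_ms: float = EPOCH_TMIN_MS,
    tmax_ms: float = EPOCH_TMAX_MS,
    participant_id: str | None = None,
) -> tuple[EpochSet, int]:
    """Slice stimulus-locked epochs out of (channels, samples) data.

    Only events flagged correct (when ``correct_mask`` is given) are epoched;
    events without enough context are skipped with a warning.  Returns the
    EpochSet and the number of skipped events.
    """
    x = np.asarray(continuous, dtype=np.float64)
    pre = int(round(-tmin_ms * rate / 1000.0))
    n_samp = int(round((tmax_ms - tmin_ms) * rate / 1000.0))
    events = list(events)
    if correct_mask is not None:
        if len(correct_mask) != len(events):
            raise ValueError("correct_mask must align with events")
        events = [e for e, ok in zip(events, correct_mask) if ok]
    epochs, skipped = [], 0
    for onset in events:
        start = onset - pre
        if start < 0 or start + n_samp > x.shape[1]:
            log.warning("event at sample %d lacks context; epoch skipped", onset)
            skipped += 1
            continue
        epochs.append(x[:, start : start + n_samp])
    data = np.stack(epochs) if epochs else np.empty((0, x.shape[0], n_samp))
    eset = EpochSet(data, tuple(channel_names), rate, condition,
                    t_start_ms=tmin_ms, participant_id=participant_id)
    return eset, skipped


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the per-epoch, per-channel mean of the baseline window."""
    lo, hi = epochs.baseline_window_ms
    i0, i1 = epochs.sample_of_ms(lo), epochs.sample_of_ms(hi)
    if i0 < 0 or i1 > epochs.n_samples or i1 <= i0:
        raise PreprocessingError("baseline window outside epoch")
    base = epochs.data[:, :, i0:i1].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base)


def reject_epochs(epochs: EpochSet, threshold_uv: float = REJECT_UV) -> tuple[EpochSet, int]:
    """Drop epochs in which any sample strictly exceeds +-threshold."""
    peak = np.abs(epochs.data).max(axis=(1, 2)) if epochs.n_epochs else np.empty(0)
    keep = peak <= threshold_uv
    n_rejected = int((~keep).sum())
    if epochs.n_epochs and not keep.any():
        raise AllEpochsRejected(
            f"all {epochs.n_epochs} epochs rejected for "
            f"{epochs.participant_id}/{epochs.condition}"
        )
    return replace(epochs, data=epochs.data[keep]), n_rejected


def resample_epochs(epochs: EpochSet, to_rate: float) -> EpochSet:
    if to_rate == epochs.sampling_rate_hz:
        return epochs
    data = downsample(epochs.data, epochs.sampling_rate_hz, to_rate)
    return replace(epochs, data=data, sampling_rate_hz=to_rate)


def preprocess_epochs(
    epochs: EpochSet,
    to_rate: float = 500.0,
    reject_uv: float = REJECT_UV,
) -> tuple[EpochSet, int]:
    """Epoch-form pipeline: resample -> baseline correct -> amplitude reject."""
    out = resample_epochs(epochs, to_rate)
    out = baseline_correct(out)
    return reject_epochs(out, reject_uv)


def preprocess_continuous(
    continuous: np.ndarray,
    rate: float,
    events: Sequence[int],
    channel_names: Sequence[str],
    condition: str,
    correct_mask: Sequence[bool] | None = None,
    to_rate: float = 500.0,
    band: tuple[float, float] = (3.0, 40.0),
    reject_uv: float = REJECT_UV,
    participant_id: str | None = None,
) -> tuple[EpochSet, int, int]:
    """Full continuous pipeline; returns (kept epochs, n_rejected, n_skipped).

    Event sample indices are given at the *input* rate and are rescaled after
    downsampling.
    """
    x = downsample(continuous, rate, to_rate)
    x = bandpass_filter(x, to_rate, band)
    scale = to_rate / rate
    events_ds = [int(round(e * scale)) for e in events]
    eset, skipped = extract_epochs(
        x, events_ds, to_rate, channel_names, condition,
        correct_mask=correct_mask, participant_id=participant_id,
    )
    eset = baseline_correct(eset)
    kept, n_rejected = reject_epochs(eset, reject_uv)
    return kept, n_rejected, skipped
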