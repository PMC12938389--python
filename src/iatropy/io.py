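"""Cohort serialization and EEG file readers.

On-disk cohort layout: one directory per participant containing a flat
binary epoch array (.npy) plus a JSON sidecar per condition (channel names,
sampling rate, epoch count, time offsets), the trial log and the exercise
recall as TSV.  EDF/BrainVision readers for real recordings are thin
wrappers over MNE (an optional dependency, imported lazily).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import ExerciseReport, TrialRecord
from .preprocessing import EpochSet
from .synthetic import ParticipantRecord

TRIAL_COLUMNS = ["participant_id", "iat_type", "block", "practice", "rt_ms", "correct"]
EXERCISE_COLUMNS = [
    "participant_id", "walking_days", "walking_min", "moderate_days",
    "moderate_min", "vigorous_days", "vigorous_min",
]


def trial_log_frame(pid: str, trials: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "participant_id": pid, "iat_type": t.iat_type, "block": t.block,
            "practice": t.practice,
            "rt_ms": np.nan if t.rt_ms is None else t.rt_ms,
            "correct": t.correct,
        }
        for t in trials
    ], columns=TRIAL_COLUMNS)


def frame_trial_log(df: pd.DataFrame) -> list[TrialRecord]:
    out = []
    for _, r in df.iterrows():
        rt = r["rt_ms"]
        rt_val = None if (pd.isna(rt) or rt == "") else float(rt)
        out.append(TrialRecord(str(r["iat_type"]), str(r["block"]),
                               bool(r["practice"]), rt_val, bool(r["correct"])))
    return out


def save_cohort(cohort: Sequence[ParticipantRecord], out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = []
    for rec in cohort:
        pdir = out_dir / rec.participant_id
        pdir.mkdir(exist_ok=True)
        for condition, eset in rec.epoch_sets.items():
            np.save(pdir / f"{condition}.npy", eset.data)
            sidecar = {
                "channel_names": list(eset.channel_names),
                "sampling_rate_hz": eset.sampling_rate_hz,
                "n_epochs": eset.n_epochs,
                "t_start_ms": eset.t_start_ms,
                "baseline_window_ms": list(eset.baseline_window_ms),
                "condition": condition,
            }
            (pdir / f"{condition}.json").write_text(json.dumps(sidecar, indent=1))
        trial_log_frame(rec.participant_id, rec.trial_log).to_csv(
            pdir / "trials.tsv", sep="\t", index=False, float_format="%.17g")
        rep = rec.exercise_report
        pd.DataFrame([{"participant_id": rec.participant_id,
                       **{c: getattr(rep, c) for c in EXERCISE_COLUMNS[1:]}}]).to_csv(
            pdir / "exercise.tsv", sep="\t", index=False, float_format="%.17g")
        labels.append({"participant_id": rec.participant_id, "group": rec.group_label})
    pd.DataFrame(labels).to_csv(out_dir / "groups.tsv", sep="\t", index=False)
    return out_dir


def load_cohort(cohort_dir: str | Path) -> list[ParticipantRecord]:
    cohort_dir = Path(cohort_dir)
    groups = pd.read_csv(cohort_dir / "groups.tsv", sep="\t").set_index("participant_id")["group"]
    cohort = []
    for pid, group in groups.items():
        pdir = cohort_dir / str(pid)
        epoch_sets = {}
        for sidecar_path in sorted(pdir.glob("*.json")):
            meta = json.loads(sidecar_path.read_text())
            data = np.load(pdir / f"{meta['condition']}.npy")
            epoch_sets[meta["condition"]] = EpochSet(
                data, tuple(meta["channel_names"]), meta["sampling_rate_hz"],
                meta["condition"], t_start_ms=meta["t_start_ms"],
                baseline_window_ms=tuple(meta["baseline_window_ms"]),
                participant_id=str(pid),
            )
        trials = frame_trial_log(pd.read_csv(pdir / "trials.tsv", sep="\t",
                                             float_precision="round_trip"))
        ex = pd.read_csv(pdir / "exercise.tsv", sep="\t",
                         float_precision="round_trip").iloc[0]
        report = ExerciseReport(**{c: float(ex[c]) for c in EXERCISE_COLUMNS[1:]})
        cohort.append(ParticipantRecord(str(pid), str(group), epoch_sets, trials, report))
    return cohort


def read_continuous_eeg(path: str | Path):
    """Read continuous EEG (EDF or BrainVision) via MNE.

    Returns (data_uv, sampling_rate_hz, channel_names, event_samples).
    """
    import mne  # optional dependency

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG format {path.suffix!r} (use .edf or .vhdr)")
    events, _ = mne.events_from_annotations(raw, verbose="error")
    data_uv = raw.get_data() * 1e6
    return data_uv, float(raw.info["sfreq"]), list(raw.ch_names), list(events[:, 0])
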