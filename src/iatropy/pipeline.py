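"""End-to-end orchestration: synth -> score -> preprocess -> features ->
compare -> classify, with a JSON run manifest for reproducibility.

A single root seed is fanned out to the cohort generator and the classifier
protocol through named substreams.  Stage outputs are written to temporary
names and atomically renamed, so a failed run leaves no half-written files
under their final names.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .behavior import compute_met_minutes, score_iat
from .classify import CLASSIFIERS, EvalProtocol, ExerciseClassifier, FeatureSetSpec
from .entropy import EntropyConfig
from .features import compute_feature_table, config_hash
from .montage import IAT_TYPES
from .preprocessing import AllEpochsRejected, preprocess_epochs
from .rng import child_seeds
from .stats import EntropyGroupComparison
from .synthetic import CohortSpec, cohort_labels, generate_cohort

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortSpec = CohortSpec()
    entropy: EntropyConfig = EntropyConfig()
    analysis_rate_hz: float = 500.0
    reject_uv: float = 100.0
    q: float = 0.05
    protocol: EvalProtocol = EvalProtocol()
    classifiers: tuple[str, ...] = ("RF",)
    feature_spec: FeatureSetSpec = FeatureSetSpec("envelope_only", "affective", "incompatible")
    output_dir: str = "iatropy-run"
    root_seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.analysis_rate_hz <= 0:
            raise ValueError("analysis_rate_hz must be positive")
        for c in self.classifiers:
            if c not in CLASSIFIERS:
                raise ValueError(f"unknown classifier {c!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortSpec(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in kwargs["cohort"].items()
            })
        if "entropy" in kwargs:
            kwargs["entropy"] = EntropyConfig(**kwargs["entropy"])
        if "protocol" in kwargs:
            kwargs["protocol"] = EvalProtocol(**kwargs["protocol"])
        if "feature_spec" in kwargs:
            kwargs["feature_spec"] = FeatureSetSpec(**kwargs["feature_spec"])
        if "classifiers" in kwargs:
            kwargs["classifiers"] = tuple(kwargs["classifiers"])
        return cls(**kwargs)


def _cfg_hash(config: RunConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("output_dir", None)  # hash identifies the analysis, not its location
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_atomic(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_name(path.name + ".partial")
    df.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _cfg_hash(config),
        "entropy_config_hash": config_hash(config.entropy),
        "root_seed": config.root_seed,
        "stages": {},
    }

    spec = dataclasses.replace(config.cohort, seed=child_seeds(config.root_seed, 1, "cohort")[0])
    cohort = generate_cohort(spec)
    labels = cohort_labels(cohort)
    manifest["stages"]["synth"] = {
        "n_participants": len(cohort),
        "n_exercise": sum(1 for g in labels.values() if g == "exercise"),
    }

    behavior_rows, group_rows = [], []
    for rec in cohort:
        for iat in IAT_TYPES:
            res = score_iat([t for t in rec.trial_log if t.iat_type == iat])
            behavior_rows.append({
                "participant_id": rec.participant_id, "iat_type": iat,
                "d_score": res.d_score, "n_trials_used": res.n_trials_used,
                "excluded": res.excluded_participant, "reason": res.exclusion_reason,
            })
        met = compute_met_minutes(rec.exercise_report)
        group_rows.append({"participant_id": rec.participant_id,
                           "group": rec.group_label, **met})
    dscores = pd.DataFrame(behavior_rows)
    _write_atomic(dscores, out / "dscores.tsv")
    _write_atomic(pd.DataFrame(group_rows), out / "groups.tsv")
    manifest["stages"]["score_behavior"] = {
        "n_excluded": int(dscores["excluded"].sum()),
        "mean_d_affective": float(
            dscores.query("iat_type == 'affective' and not excluded")["d_score"].mean()),
    }

    clean, n_rejected = [], 0
    for rec in cohort:
        for condition, eset in rec.epoch_sets.items():
            try:
                kept, rej = preprocess_epochs(eset, config.analysis_rate_hz, config.reject_uv)
            except AllEpochsRejected:
                log.warning("all epochs rejected: %s/%s", rec.participant_id, condition)
                continue
            n_rejected += rej
            clean.append(kept)
    manifest["stages"]["preprocess"] = {
        "n_epoch_sets": len(clean), "n_epochs_rejected": n_rejected,
        "analysis_rate_hz": config.analysis_rate_hz,
    }

    table = compute_feature_table(clean, config.entropy)
    _write_atomic(table, out / "features.tsv")
    manifest["stages"]["features"] = {
        "n_rows": len(table), "config_hash": table.attrs["config_hash"],
    }

    stats_res = EntropyGroupComparison(table, labels).fit(config.q)
    _write_atomic(stats_res.stat_table, out / "group_stats.tsv")
    manifest["stages"]["compare"] = {
        "family_sizes": stats_res.stat_table.attrs["family_sizes"],
        "n_significant": int(stats_res.stat_table["significant"].sum()),
    }

    clf_seed = child_seeds(config.root_seed, 1, "classify")[0]
    clf_summaries = {}
    for name in config.classifiers:
        model = ExerciseClassifier.from_feature_table(
            table, labels, config.feature_spec, name, config.protocol, dscores=dscores)
        res = model.fit(clf_seed)
        clf_summaries[name] = {
            "metrics_mean": res.metrics_mean, "metrics_sd": res.metrics_sd, "auc": res.auc,
        }
        (out / f"classification_{name}.txt").write_text(res.summary() + "\n")
        _write_atomic(res.roc_points, out / f"roc_{name}.tsv")
        if res.importances is not None:
            _write_atomic(res.top5_importances(), out / f"importances_{name}.tsv")
    manifest["stages"]["classify"] = clf_summaries

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
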