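"""Participant x condition x region x metric entropy feature tables.

Each metric is evaluated per epoch x electrode on the configured segment of
the epoch (full -500..1000 ms by default), averaged across epochs, then
averaged across the electrodes of each scalp region.  Sample-entropy values
that are undefined (no template matches) are excluded from the averages and
counted in ``n_undefined``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .entropy import (DEFAULT_CONFIG, METRICS, EntropyConfig, batch_apen_sampen,
                      compute_metric, effective_config)
from .montage import CONDITIONS, REGION_MAP, REGIONS
from .preprocessing import EpochSet

log = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "participant_id", "condition", "region", "metric", "value", "n_epochs", "n_undefined",
]


def config_hash(cfg: EntropyConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def segment_slice(eset: EpochSet, cfg: EntropyConfig) -> slice:
    if cfg.segment == "full_epoch":
        return slice(0, eset.n_samples)
    return slice(eset.sample_of_ms(0.0), eset.n_samples)  # post-stimulus 0..end


def epoch_set_features(
    eset: EpochSet,
    cfg: EntropyConfig = DEFAULT_CONFIG,
    metrics: Sequence[str] = METRICS,
    region_map: Mapping[str, tuple[str, ...]] = REGION_MAP,
) -> list[dict]:
    """Rows of the feature table for one participant x condition."""
    if eset.n_epochs == 0:
        log.warning("no epochs for %s/%s; rows omitted", eset.participant_id, eset.condition)
        return []
    sl = segment_slice(eset, cfg)
    seg = eset.data[:, :, sl]
    n_ep, n_ch, n_samp = seg.shape
    cfg_eff = effective_config(cfg, n_samp) if "singular_spectrum" in metrics else cfg
    ch_index = {ch: i for i, ch in enumerate(eset.channel_names)}
    rows: list[dict] = []
    flat = np.ascontiguousarray(seg.reshape(n_ep * n_ch, n_samp))
    cache: dict[str, np.ndarray] = {}
    if "approximate" in metrics and "sample" in metrics:
        cache["approximate"], cache["sample"] = batch_apen_sampen(flat, cfg_eff)
    for metric in metrics:
        raw = cache[metric] if metric in cache else compute_metric(metric, flat, cfg_eff)
        vals = raw.reshape(n_ep, n_ch)
        with warnings.catch_warnings():
            # all-undefined channels (SampEn with no matches) yield NaN means
            warnings.simplefilter("ignore", RuntimeWarning)
            ch_mean = np.nanmean(vals, axis=0)
        n_undef = int(np.isnan(vals).sum())
        for region in region_map:
            cols = [ch_index[ch] for ch in region_map[region] if ch in ch_index]
            if not cols:
                log.warning("region %s has no channels in %s; skipped", region, eset.participant_id)
                continue
            rows.append({
                "participant_id": eset.participant_id,
                "condition": eset.condition,
                "region": region,
                "metric": metric,
                "value": float(np.mean(ch_mean[cols])),
                "n_epochs": n_ep,
                "n_undefined": n_undef,
            })
    return rows


def compute_feature_table(
    epoch_sets: Iterable[EpochSet],
    cfg: EntropyConfig = DEFAULT_CONFIG,
    metrics: Sequence[str] = METRICS,
    region_map: Mapping[str, tuple[str, ...]] = REGION_MAP,
) -> pd.DataFrame:
    """Long-format feature table over a collection of EpochSets.

    Columns: participant_id, condition, region, metric, value, n_epochs,
    n_undefined.  The table carries the entropy-config hash in
    ``df.attrs["config_hash"]`` for provenance.
    """
    rows: list[dict] = []
    for eset in epoch_sets:
        rows.extend(epoch_set_features(eset, cfg, metrics, region_map))
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.attrs["config_hash"] = config_hash(cfg)
    return df


def to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot to one row per participant; columns condition|region|metric.

    Column order is condition-major, region-minor, metric-innermost.
    """
    wide = table.pivot_table(
        index="participant_id",
        columns=["condition", "region", "metric"],
        values="value",
        sort=False,
    )
    ordered = [
        (c, r, m)
        for c in CONDITIONS for r in REGIONS for m in METRICS
        if (c, r, m) in wide.columns
    ]
    wide = wide[ordered]
    wide.columns = ["|".join(col) for col in wide.columns]
    return wide
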