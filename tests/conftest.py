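"""Shared fixtures: scaled-down cohorts so Monte-Carlo tests stay desk-sized.

The scaled conditions keep the study design (56 participants, 33/23 split,
four conditions, 14 electrodes, the full seven-metric panel) but shrink the
problem size: 200 Hz native / 100 Hz analysis rate, a handful of formal
trials per block, post-stimulus entropy segment and an SSE window matched
to the shorter segment.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from iatropy.entropy import EntropyConfig
from iatropy.features import compute_feature_table
from iatropy.preprocessing import preprocess_epochs
from iatropy.stats import compare_groups
from iatropy.synthetic import CohortSpec, cohort_labels, generate_cohort

logging.getLogger("iatropy").setLevel(logging.ERROR)

SCALED_RATE_HZ = 200.0
ANALYSIS_RATE_HZ = 100.0
SCALED_ENTROPY = EntropyConfig(sse_window=30, segment="post_stimulus")


def scaled_spec(seed: int, *, trials: int = 4, effect_size_d: float = 1.0, **kw) -> CohortSpec:
    return CohortSpec(
        sampling_rate_hz=SCALED_RATE_HZ,
        n_trials_per_block=trials,
        n_practice_per_block=2,
        seed=seed,
        effect_size_d=effect_size_d,
        **kw,
    )


def cohort_features(cohort, cfg=SCALED_ENTROPY, metrics=None, conditions=None):
    """Preprocess + feature-extract a generated cohort (scaled analysis rate)."""
    from iatropy.entropy import METRICS

    clean = []
    for rec in cohort:
        for condition, eset in rec.epoch_sets.items():
            if conditions is not None and condition not in conditions:
                continue
            kept, _ = preprocess_epochs(eset, ANALYSIS_RATE_HZ)
            clean.append(kept)
    return compute_feature_table(clean, cfg, metrics=metrics or METRICS)


def run_scaled_pipeline(seed: int, *, trials: int = 4, effect_size_d: float = 1.0):
    """generate -> preprocess -> features -> group stats; returns (stat_table, labels, table)."""
    cohort = generate_cohort(scaled_spec(seed, trials=trials, effect_size_d=effect_size_d))
    table = cohort_features(cohort)
    labels = cohort_labels(cohort)
    return compare_groups(table, labels), labels, table


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort (8 exercise / 6 non-exercise) for structural tests."""
    return generate_cohort(scaled_spec(11, trials=3, n_exercise=8, n_nonexercise=6))


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    return cohort_features(tiny_cohort)
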