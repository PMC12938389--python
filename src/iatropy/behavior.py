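"""IAT D-score computation and IPAQ exercise scoring.

The D-score standardizes the reaction-time (RT) cost of the incompatible
block relative to the compatible block of an implicit association test::

    D = (mean RT_incompatible - mean RT_compatible) / pooled SD

Preprocessing order: practice trials are removed; formal trials with RT
below 350 ms or a missing response are discarded; participants whose error
rate in either block of an IAT exceeds 20% are excluded from that IAT;
incorrect trials then receive an RT penalty (block mean of correct retained
trials + 400 ms); the pooled SD is taken over the *correct* retained trials
of both blocks (their raw RTs).

Exercise behavior is scored from a 7-day recall: MET-min/week per activity
class equals MET value x min/day x days/week (walking 3.3, moderate 4.0,
vigorous 8.0 METs).  Moderate-to-vigorous (MVPA) MET-minutes exclude
walking; a participant is labelled ``non_exercise`` iff MVPA == 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .montage import BLOCKS, IAT_TYPES

RT_FLOOR_MS = 350.0
ERROR_PENALTY_MS = 400.0
MAX_ERROR_RATE = 0.20

MET_WALKING = 3.3
MET_MODERATE = 4.0
MET_VIGOROUS = 8.0


class ScoringError(ValueError):
    """Raised when a score is undefined for the given trials."""


@dataclass(frozen=True)
class TrialRecord:
    """One IAT trial."""

    iat_type: str  # affective | instrumental
    block: str  # compatible | incompatible
    practice: bool
    rt_ms: float | None  # None = missing response
    correct: bool

    def __post_init__(self) -> None:
        if self.iat_type not in IAT_TYPES:
            raise ValueError(f"unknown iat_type {self.iat_type!r}")
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}")
        if self.rt_ms is not None and self.rt_ms < 0:
            raise ValueError("rt_ms must be non-negative")


@dataclass(frozen=True)
class FilterResult:
    retained: tuple[TrialRecord, ...]
    participant_ok: bool
    reason: str = ""


@dataclass(frozen=True)
class DScoreResult:
    iat_type: str
    d_score: float | None
    n_trials_used: int
    excluded_participant: bool
    exclusion_reason: str = ""


@dataclass(frozen=True)
class ExerciseReport:
    """7-day recall of leisure-time activity (days/week and min/day)."""

    walking_days: float = 0.0
    walking_min: float = 0.0
    moderate_days: float = 0.0
    moderate_min: float = 0.0
    vigorous_days: float = 0.0
    vigorous_min: float = 0.0

    def __post_init__(self) -> None:
        for name in ("walking", "moderate", "vigorous"):
            days = getattr(self, f"{name}_days")
            mins = getattr(self, f"{name}_min")
            if days < 0 or mins < 0:
                raise ValueError(f"{name}: days and minutes must be non-negative")
            if days > 7:
                raise ValueError(f"{name}_days must be at most 7")


@dataclass(frozen=True)
class GroupLabel:
    label: str  # exercise | non_exercise
    mvpa_met_min_week: float


def filter_trials(trials: Iterable[TrialRecord]) -> FilterResult:
    """Apply the trial-level filters for one participant, one IAT type.

    Practice trials are dropped; formal trials with missing RT or RT below
    350 ms are dropped.  The participant is flagged not-ok when the error
    rate (incorrect / formal trials) exceeds 20% in either block, or when a
    block has no formal trials at all.
    """
    trials = tuple(trials)
    iat_types = {t.iat_type for t in trials}
    if len(iat_types) > 1:
        raise ValueError("filter_trials expects trials from a single IAT type")
    formal = [t for t in trials if not t.practice]
    if not formal:
        return FilterResult((), False, "no formal trials")
    retained = tuple(
        t for t in formal if t.rt_ms is not None and t.rt_ms >= RT_FLOOR_MS
    )
    for block in BLOCKS:
        block_formal = [t for t in formal if t.block == block]
        if not block_formal:
            return FilterResult(retained, False, f"no formal trials in {block} block")
        err = sum(not t.correct for t in block_formal) / len(block_formal)
        if err > MAX_ERROR_RATE:
            return FilterResult(
                retained, False, f"error rate {err:.1%} in {block} block exceeds 20%"
            )
    return FilterResult(retained, True)


def apply_error_penalty(retained: Sequence[TrialRecord], block: str) -> tuple[TrialRecord, ...]:
    """Replace incorrect-trial RTs by (mean correct RT of the block) + 400 ms."""
    block_trials = [t for t in retained if t.block == block]
    correct_rts = [t.rt_ms for t in block_trials if t.correct]
    if any(not t.correct for t in block_trials) and not correct_rts:
        raise ScoringError(f"{block} block has no correct trials; penalty undefined")
    penalty = (float(np.mean(correct_rts)) + ERROR_PENALTY_MS) if correct_rts else None
    out = []
    for t in block_trials:
        out.append(t if t.correct else replace(t, rt_ms=penalty))
    return tuple(out)


def compute_dscore(
    compatible: Sequence[TrialRecord],
    incompatible: Sequence[TrialRecord],
    *,
    sd_mode: str = "union",
) -> float:
    """D = (mean incompatible RT - mean compatible RT) / pooled SD.

    RT means use effective (penalty-adjusted) RTs of all retained trials; the
    pooled SD is computed from the raw RTs of *correct* trials only.
    ``sd_mode="union"`` (default) takes the sample SD (n-1 denominator) of
    the union of correct-trial RTs from both blocks; ``"two_sample"`` uses
    the classical two-sample pooled estimator.
    """
    if not compatible or not incompatible:
        raise ScoringError("both blocks must be non-empty after filtering")
    mean_c = float(np.mean([t.rt_ms for t in compatible]))
    mean_i = float(np.mean([t.rt_ms for t in incompatible]))
    rts_c = np.array([t.rt_ms for t in compatible if t.correct], dtype=float)
    rts_i = np.array([t.rt_ms for t in incompatible if t.correct], dtype=float)
    if rts_c.size + rts_i.size < 2:
        raise ScoringError("fewer than two correct trials; SD undefined")
    if sd_mode == "union":
        sd = float(np.std(np.concatenate([rts_c, rts_i]), ddof=1))
    elif sd_mode == "two_sample":
        if rts_c.size < 2 or rts_i.size < 2:
            raise ScoringError("two-sample pooled SD needs >=2 correct trials per block")
        sd = math.sqrt(
            ((rts_c.size - 1) * np.var(rts_c, ddof=1) + (rts_i.size - 1) * np.var(rts_i, ddof=1))
            / (rts_c.size + rts_i.size - 2)
        )
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    if sd == 0:
        raise ScoringError("pooled SD is zero; D-score undefined")
    return (mean_i - mean_c) / sd


def score_iat(trials: Iterable[TrialRecord], *, sd_mode: str = "union") -> DScoreResult:
    """Full D-score chain (filter -> error-rate check -> penalty -> D) for one IAT."""
    trials = tuple(trials)
    iat_type = trials[0].iat_type if trials else "affective"
    filt = filter_trials(trials)
    if not filt.participant_ok:
        return DScoreResult(iat_type, None, 0, True, filt.reason)
    try:
        compat = apply_error_penalty(filt.retained, "compatible")
        incompat = apply_error_penalty(filt.retained, "incompatible")
        d = compute_dscore(compat, incompat, sd_mode=sd_mode)
    except ScoringError as exc:
        return DScoreResult(iat_type, None, 0, True, str(exc))
    return DScoreResult(iat_type, d, len(compat) + len(incompat), False)


def compute_met_minutes(report: ExerciseReport) -> dict[str, float]:
    """MET-min/week per activity class; ``mvpa_total`` excludes walking."""
    walking = MET_WALKING * report.walking_min * report.walking_days
    moderate = MET_MODERATE * report.moderate_min * report.moderate_days
    vigorous = MET_VIGOROUS * report.vigorous_min * report.vigorous_days
    return {
        "walking": walking,
        "moderate": moderate,
        "vigorous": vigorous,
        "mvpa_total": moderate + vigorous,
    }


def assign_group(report: ExerciseReport) -> GroupLabel:
    """``non_exercise`` iff moderate-to-vigorous MET-min/week equals zero."""
    mvpa = compute_met_minutes(report)["mvpa_total"]
    return GroupLabel("non_exercise" if mvpa == 0 else "exercise", mvpa)
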