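"""Questionnaire, performance and physiological stress scoring.

The physiological stress score of a subject in a phase is the mean of the
heart-rate and skin-conductance-level ratios to the control group's phase
means, so a control-typical subject scores 1.0 everywhere.  Per-subject
trajectories of that score over phases are classified into four
resilience-trend classes by percent change from baseline:

* resistant     - baseline-to-stressor change <= threshold (default 5%)
* resilient     - stressor change > threshold, scenario change <= threshold
* recovery      - both changes > threshold, scenarios below the stressor peak
* dysfunctional - both changes > threshold and the scenario aggregate exceeds
                  the stressor score (a continued rise)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ScoringConfig
from .session_io import MissionLog, SCENARIO_PHASES

logger = logging.getLogger(__name__)

TREND_LABELS = ("resistant", "resilient", "recovery", "dysfunctional")


class IncompleteTrajectoryError(ValueError):
    """Subject lacks the phases or channels needed for a stress trajectory."""


@dataclass
class StressTrajectory:
    """Control-normalized stress score per phase, and its percent changes."""

    subject_id: str
    score_by_phase: dict[str, float]
    pct_change_tsst: float
    pct_change_scenarios: float
    scenario_aggregate: float


@dataclass(frozen=True)
class PerformanceScore:
    scenario: int
    score: float


# ---------------------------------------------------------------------------
# questionnaire


def score_stai(items: Sequence[int],
               reverse_keyed: Sequence[int] = ()) -> int:
    """Total a 20-item state-anxiety questionnaire (range 20-80).

    Each item is rated 1-4; items listed in ``reverse_keyed`` (0-based
    indices) are mapped ``x -> 5 - x`` before summation.
    """
    items = list(items)
    if len(items) != 20:
        raise ValueError(f"expected 20 items, got {len(items)}")
    reverse = set(reverse_keyed)
    total = 0
    for i, x in enumerate(items):
        if not (isinstance(x, (int, np.integer)) and 1 <= x <= 4):
            raise ValueError(f"item {i} out of range 1-4: {x!r}")
        total += 5 - x if i in reverse else x
    return total


# ---------------------------------------------------------------------------
# mission performance


def performance_score(log: MissionLog,
                      config: ScoringConfig | None = None) -> PerformanceScore:
    """Score a mission on a 0-10 scale.

    Ten points scaled by the fraction of objectives met, minus penalties for
    shots received, civilian hits and exceeding the scenario time budget,
    clamped to [0, 10].  Penalty weights are configuration.
    """
    config = config or ScoringConfig()
    if log.objectives_total == 0:
        raise ValueError("mission log has zero objectives")
    over_time = max(0.0, log.duration_s / log.par_time_s - 1.0)
    raw = (
        10.0 * log.objectives_met / log.objectives_total
        - config.w_shot * log.times_shot
        - config.w_civ * log.civilian_hits
        - config.w_time * over_time
    )
    return PerformanceScore(scenario=log.scenario,
                            score=float(np.clip(raw, 0.0, 10.0)))


# ---------------------------------------------------------------------------
# physiological stress score


def control_phase_means(features: pd.DataFrame,
                        config: ScoringConfig | None = None) -> pd.DataFrame:
    """Per-phase control-group means of heart rate and SCL.

    With ``normalization = "grand"`` every phase gets the control group's
    grand mean instead.  Raises when a mean is missing or non-positive.
    """
    config = config or ScoringConfig()
    controls = features[features["group"] == "control"]
    if controls.empty:
        raise ValueError("no control subjects to normalize against")
    means = controls.groupby("phase")[["hr_bpm", "scl_uS"]].mean()
    if config.normalization == "grand":
        grand = controls[["hr_bpm", "scl_uS"]].mean()
        means = pd.DataFrame(
            {c: grand[c] for c in ("hr_bpm", "scl_uS")}, index=means.index
        )
    if means.isna().any().any() or (means <= 0).any().any():
        raise ValueError("control means must be strictly positive")
    return means


def _aggregate(values: Sequence[float], how: str) -> float:
    arr = np.asarray(values, dtype=float)
    if how == "mean":
        return float(np.mean(arr))
    if how == "last":
        return float(arr[-1])
    if how == "max":
        return float(np.max(arr))
    raise ValueError(f"unknown scenario aggregate {how!r}")


def stress_score(subject_features: pd.DataFrame,
                 control_means: pd.DataFrame,
                 config: ScoringConfig | None = None) -> StressTrajectory:
    """Control-normalized stress trajectory for one subject.

    ``subject_features`` holds that subject's rows of the phase feature
    table.  For each phase the score is
    ``w * hr/hr_control + (1-w) * scl/scl_control`` (default w = 0.5).
    Requires heart rate and SCL at baseline, the stressor phase, and at
    least one scenario; otherwise :class:`IncompleteTrajectoryError` — the
    study analogue is a subject dropped after losing the EDA electrode.
    """
    config = config or ScoringConfig()
    sid = str(subject_features["subject_id"].iloc[0])
    w = config.hr_weight
    scores: dict[str, float] = {}
    for _, row in subject_features.iterrows():
        phase = row["phase"]
        if phase not in control_means.index:
            continue
        hr, scl = row["hr_bpm"], row["scl_uS"]
        if not (np.isfinite(hr) and np.isfinite(scl)):
            continue
        ref = control_means.loc[phase]
        scores[phase] = float(w * hr / ref["hr_bpm"]
                              + (1 - w) * scl / ref["scl_uS"])

    missing = {"baseline", "tsst"} - scores.keys()
    scenario_scores = [scores[p] for p in SCENARIO_PHASES if p in scores]
    if missing or not scenario_scores:
        raise IncompleteTrajectoryError(
            f"subject {sid}: incomplete trajectory "
            f"(missing {sorted(missing) or 'all scenarios'})"
        )
    base = scores["baseline"]
    agg = _aggregate(scenario_scores, config.scenario_aggregate)
    return StressTrajectory(
        subject_id=sid,
        score_by_phase=scores,
        pct_change_tsst=100.0 * (scores["tsst"] - base) / base,
        pct_change_scenarios=100.0 * (agg - base) / base,
        scenario_aggregate=agg,
    )


def classify_trend(traj: StressTrajectory,
                   threshold_pct: float = 5.0) -> str:
    """Assign one of the four resilience-trend labels to a trajectory."""
    if traj.pct_change_tsst <= threshold_pct:
        return "resistant"
    if traj.pct_change_scenarios <= threshold_pct:
        return "resilient"
    if traj.scenario_aggregate > traj.score_by_phase["tsst"]:
        return "dysfunctional"
    return "recovery"


def label_cohort(features: pd.DataFrame,
                 config: ScoringConfig | None = None
                 ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label every experimental subject with a resilience trend.

    Control subjects define the normalization and are never labeled.
    Subjects with incomplete trajectories (e.g. missing SCL) are excluded
    and logged.  Returns a per-subject table (subject_id, label, the two
    percent changes) and a count per label.
    """
    config = config or ScoringConfig()
    means = control_phase_means(features, config)
    experimental = features[features["group"] == "experimental"]
    rows = []
    for sid, sub in experimental.groupby("subject_id", sort=True):
        try:
            traj = stress_score(sub, means, config)
        except IncompleteTrajectoryError as exc:
            logger.warning("excluded from trend analysis: %s", exc)
            continue
        rows.append({
            "subject_id": sid,
            "label": classify_trend(traj, config.threshold_pct),
            "pct_change_tsst": traj.pct_change_tsst,
            "pct_change_scenarios": traj.pct_change_scenarios,
        })
    labels = pd.DataFrame(
        rows, columns=["subject_id", "label",
                       "pct_change_tsst", "pct_change_scenarios"])
    counts = {lab: int((labels["label"] == lab).sum())
              for lab in TREND_LABELS}
    return labels, counts
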