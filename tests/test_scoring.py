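import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stressres import scoring
from stressres.config import ScoringConfig
from stressres.session_io import MissionLog


# ---------------------------------------------------------------------------
# questionnaire totals


def test_stai_scale_bounds():
    assert scoring.score_stai([1] * 20) == 20
    assert scoring.score_stai([4] * 20) == 80


def test_stai_alternating_items():
    items = [1, 4] * 10
    assert scoring.score_stai(items) == 50


def test_stai_reverse_keying():
    items = [1] * 20
    assert scoring.score_stai(items, reverse_keyed=range(20)) == 80
    # half the items reverse-keyed at value 2 -> 10*2 + 10*3
    assert scoring.score_stai([2] * 20, reverse_keyed=range(10)) == 50


@pytest.mark.parametrize("bad", [[1] * 19, [0] + [1] * 19, [5] + [1] * 19,
                                 [1.5] + [1] * 19])
def test_stai_rejects_malformed_items(bad):
    with pytest.raises(ValueError):
        scoring.score_stai(bad)


@settings(max_examples=100, derandomize=True)
@given(items=st.lists(st.integers(1, 4), min_size=20, max_size=20),
       rev=st.sets(st.integers(0, 19)))
def test_stai_equals_brute_force_sum(items, rev):
    brute = sum(5 - x if i in rev else x for i, x in enumerate(items))
    assert scoring.score_stai(items, reverse_keyed=rev) == brute


# ---------------------------------------------------------------------------
# mission performance


def _log(met=5, total=5, shot=0, civ=0, dur=500.0, par=600.0):
    return MissionLog("S1", 1, dur, total, met, shot, civ, par)


def test_perfect_mission_scores_ten():
    assert scoring.performance_score(_log()).score == 10.0


def test_failed_mission_clamps_to_zero():
    heavy = _log(met=0, shot=10, civ=3, dur=1800.0)
    assert scoring.performance_score(heavy).score == 0.0


def test_partial_mission_hand_arithmetic():
    # 4/5 objectives, 2 shots, at par: 8 - 1 = 7 with default weights
    log = _log(met=4, shot=2, dur=600.0)
    assert scoring.performance_score(log).score == pytest.approx(7.0)


def test_zero_objectives_rejected():
    with pytest.raises(ValueError):
        scoring.performance_score(_log(met=0, total=0))


def test_performance_monotone_in_penalties():
    base = scoring.performance_score(_log(met=4)).score
    assert scoring.performance_score(_log(met=5)).score >= base
    assert scoring.performance_score(_log(met=4, shot=1)).score <= base
    assert scoring.performance_score(_log(met=4, civ=1)).score <= base
    assert scoring.performance_score(_log(met=4, dur=900.0)).score <= base


# ---------------------------------------------------------------------------
# stress score


def _feature_table(subject_scores, control_hr=70.0, control_scl=4.0):
    """Build a feature table from {subject: {phase: (hr_ratio, scl_ratio)}}
    plus one exact-mean control subject."""
    rows = []
    phases = ["baseline", "tsst", "scenario1", "scenario2"]
    for phase in phases:
        rows.append({"subject_id": "CTL", "group": "control",
                     "phase": phase, "hr_bpm": control_hr,
                     "scl_uS": control_scl})
    for sid, ratios in subject_scores.items():
        for phase in phases:
            hr_r, scl_r = ratios.get(phase, (1.0, 1.0))
            rows.append({"subject_id": sid, "group": "experimental",
                         "phase": phase, "hr_bpm": control_hr * hr_r,
                         "scl_uS": control_scl * scl_r})
    return pd.DataFrame(rows)


def test_control_typical_subject_scores_unity():
    feats = _feature_table({"E1": {}})
    means = scoring.control_phase_means(feats)
    traj = scoring.stress_score(
        feats[feats["subject_id"] == "E1"], means)
    assert all(v == pytest.approx(1.0) for v in traj.score_by_phase.values())
    assert traj.pct_change_tsst == pytest.approx(0.0)
    assert traj.pct_change_scenarios == pytest.approx(0.0)


def test_stress_score_hand_arithmetic():
    feats = _feature_table({"E1": {"tsst": (1.2, 1.0)}})
    means = scoring.control_phase_means(feats)
    traj = scoring.stress_score(feats[feats["subject_id"] == "E1"], means)
    assert traj.score_by_phase["tsst"] == pytest.approx(1.1)
    assert traj.pct_change_tsst == pytest.approx(10.0)


def test_zero_control_scl_rejected():
    feats = _feature_table({"E1": {}}, control_scl=0.0)
    with pytest.raises(ValueError):
        scoring.control_phase_means(feats)


def test_missing_scl_excludes_subject():
    feats = _feature_table({"E1": {}})
    feats.loc[feats["subject_id"] == "E1", "scl_uS"] = np.nan
    means = scoring.control_phase_means(feats)
    with pytest.raises(scoring.IncompleteTrajectoryError):
        scoring.stress_score(feats[feats["subject_id"] == "E1"], means)


# ---------------------------------------------------------------------------
# trend rules


def _traj(d_tsst, d_scen, base=1.0):
    tsst = base * (1 + d_tsst / 100)
    scen = base * (1 + d_scen / 100)
    return scoring.StressTrajectory(
        "S1", {"baseline": base, "tsst": tsst, "scenario1": scen},
        pct_change_tsst=d_tsst, pct_change_scenarios=d_scen,
        scenario_aggregate=scen)


@pytest.mark.parametrize("d_tsst,d_scen,expect", [
    (4.0, 4.0, "resistant"),
    (20.0, 2.0, "resilient"),
    (20.0, 12.0, "recovery"),
    (20.0, 35.0, "dysfunctional"),
    (5.0, 50.0, "resistant"),    # boundary: <= threshold
])
def test_trend_rule_worked_examples(d_tsst, d_scen, expect):
    assert scoring.classify_trend(_traj(d_tsst, d_scen)) == expect


@settings(max_examples=200, derandomize=True)
@given(d_tsst=st.floats(-50, 100), d_scen=st.floats(-50, 100),
       c=st.floats(0.1, 10))
def test_trend_label_scale_invariant_and_exhaustive(d_tsst, d_scen, c):
    a = scoring.classify_trend(_traj(d_tsst, d_scen, base=1.0))
    b = scoring.classify_trend(_traj(d_tsst, d_scen, base=c))
    assert a == b
    assert a in scoring.TREND_LABELS


@settings(max_examples=100, derandomize=True)
@given(d_scen=st.floats(-50, 100), lo=st.floats(-4.9, 5.0),
       hi=st.floats(5.01, 100))
def test_crossing_threshold_only_leaves_resistant(d_scen, lo, hi):
    before = scoring.classify_trend(_traj(lo, d_scen))
    after = scoring.classify_trend(_traj(hi, d_scen))
    assert before == "resistant"
    assert after != "resistant"


def test_label_cohort_controls_never_labeled():
    feats = _feature_table({})
    feats["group"] = "control"
    labels, counts = scoring.label_cohort(feats)
    assert labels.empty
    assert sum(counts.values()) == 0


def test_label_cohort_single_subject():
    feats = _feature_table({"E1": {"tsst": (1.3, 1.3)}})
    labels, counts = scoring.label_cohort(feats)
    assert len(labels) == 1
    assert counts["resilient"] == 1


def test_scenario_aggregate_modes():
    feats = _feature_table(
        {"E1": {"tsst": (1.3, 1.3), "scenario1": (1.0, 1.0),
                "scenario2": (1.2, 1.2)}})
    means = scoring.control_phase_means(feats)
    sub = feats[feats["subject_id"] == "E1"]
    mean_cfg = ScoringConfig(scenario_aggregate="mean")
    last_cfg = ScoringConfig(scenario_aggregate="last")
    max_cfg = ScoringConfig(scenario_aggregate="max")
    assert scoring.stress_score(sub, means, mean_cfg
                                ).scenario_aggregate == pytest.approx(1.1)
    assert scoring.stress_score(sub, means, last_cfg
                                ).scenario_aggregate == pytest.approx(1.2)
    assert scoring.stress_score(sub, means, max_cfg
                                ).scenario_aggregate == pytest.approx(1.2)
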