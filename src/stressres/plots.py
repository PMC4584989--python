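"""SVG plots of stress trajectories and classifier decision boundaries."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .pipeline import CohortAnalysis  # noqa: E402
from .scoring import control_phase_means, stress_score  # noqa: E402
from .session_io import PHASE_NAMES  # noqa: E402

LABEL_COLORS = {"resistant": "tab:green", "resilient": "tab:blue",
                "recovery": "tab:orange", "dysfunctional": "tab:red"}


def plot_trajectories(analysis: CohortAnalysis, path: str | Path) -> Path:
    """Mean control-normalized stress score per phase, by group."""
    means = control_phase_means(analysis.features)
    fig, ax = plt.subplots(figsize=(6, 4))
    for group, style in (("control", "--"), ("experimental", "-")):
        sub = analysis.features[analysis.features["group"] == group]
        rows = []
        for sid, s in sub.groupby("subject_id"):
            try:
                traj = stress_score(s, means)
            except ValueError:
                continue
            rows.append(traj.score_by_phase)
        if rows:
            df = pd.DataFrame(rows).reindex(columns=list(PHASE_NAMES))
            ax.plot(df.columns, df.mean(), style, marker="o", label=group)
    ax.axhline(1.0, color="gray", lw=0.5)
    ax.set_ylabel("stress score (control-normalized)")
    ax.legend()
    fig.autofmt_xdate(rotation=30)
    path = Path(path)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
    return path


def plot_decision_boundary(analysis: CohortAnalysis,
                           path: str | Path) -> Path:
    """Classifier regions in the (cortisol, anxiety) plane with the
    training subjects overlaid; outliers drawn as open markers."""
    if analysis.classifier is None:
        raise ValueError("no fitted classifier to plot")
    res = analysis.classifier
    grid = res.decision_grid(n=150)
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    for label, color in LABEL_COLORS.items():
        region = grid[grid["predicted"] == label]
        if not region.empty:
            ax.scatter(region.iloc[:, 0], region.iloc[:, 1], s=2,
                       color=color, alpha=0.12, linewidths=0)
    frame = analysis.classifier_frame
    for label, color in LABEL_COLORS.items():
        pts = frame[(frame["label"] == label) & ~frame["outlier_flag"]]
        ax.scatter(pts["cortisol_baseline"], pts["stai_baseline"],
                   color=color, edgecolor="k", s=40, label=label)
        out = frame[(frame["label"] == label) & frame["outlier_flag"]]
        ax.scatter(out["cortisol_baseline"], out["stai_baseline"],
                   facecolor="none", edgecolor=color, s=60, marker="s")
    ax.set_xlabel("baseline cortisol (ug/dl)")
    ax.set_ylabel("baseline state anxiety")
    ax.legend(fontsize=8)
    path = Path(path)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
    return path
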