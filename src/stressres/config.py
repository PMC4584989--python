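"""Analysis configuration.

Every filter order, band edge, threshold and window used by the pipeline is
surfaced here so a run can be reproduced from its config snapshot alone.
Configs serialize to a flat ``section.key<TAB>value`` text file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


@dataclass
class FeatureConfig:
    """Knobs for autonomic feature extraction.

    Frequency bands are in Hz, thresholds in the channel's native unit
    (EDA in microsiemens).
    """

    ecg_band_hz: tuple[float, float] = (5.0, 15.0)
    ecg_filter_order: int = 4
    rr_valid_bpm: tuple[float, float] = (40.0, 180.0)
    sdnn_ddof: int = 0          # population SD
    sdnn_min_window_s: float = 300.0
    hrv_resample_hz: float = 4.0
    hrv_segment_s: float = 64.0
    hrv_overlap: float = 0.5
    lf_band_hz: tuple[float, float] = (0.04, 0.15)
    hf_band_hz: tuple[float, float] = (0.15, 0.4)
    resp_band_hz: tuple[float, float] = (0.05, 1.0)
    resp_filter_order: int = 4
    eda_phasic_band_hz: tuple[float, float] = (0.05, 1.0)
    eda_filter_order: int = 4
    edr_onset_uS: float = 0.05
    edr_hysteresis_uS: float = 0.001
    edr_refractory_s: float = 1.0
    scl_lowpass_hz: float = 0.05
    emg_block_samples: int = 100


@dataclass
class ScoringConfig:
    """Stress-score combination, trend rule and performance-score weights."""

    hr_weight: float = 0.5                  # SCL weight is 1 - hr_weight
    normalization: str = "per_phase"        # "per_phase" | "grand"
    threshold_pct: float = 5.0
    scenario_aggregate: str = "mean"        # "mean" | "last" | "max"
    w_shot: float = 0.5
    w_civ: float = 2.0
    w_time: float = 2.0


@dataclass
class ClassifierConfig:
    """Hyperparameters of the baseline-biomarker trend classifier.

    Defaults pin the hinge-loss SGD configuration (L2 penalty weight
    alpha = 1e-4, the "optimal" learning-rate schedule) so the fit does not
    drift with library defaults.
    """

    loss: str = "hinge"
    alpha: float = 1e-4
    learning_rate: str = "optimal"
    max_iter: int = 1000
    tol: float = 1e-3
    standardize: bool = True
    outlier_z_cut: float = 2.2
    seed: int = 0


@dataclass
class AnalysisConfig:
    features: FeatureConfig = field(default_factory=FeatureConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def to_flat(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for section in dataclasses.fields(self):
            sub = getattr(self, section.name)
            for f in dataclasses.fields(sub):
                out[f"{section.name}.{f.name}"] = getattr(sub, f.name)
        return out

    def save(self, path: str | Path) -> None:
        lines = []
        for key, val in sorted(self.to_flat().items()):
            if isinstance(val, tuple):
                val = ",".join(repr(v) for v in val)
            lines.append(f"{key}\t{val}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        cfg = cls()
        for raw in Path(path).read_text().splitlines():
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            key, _, text = raw.partition("\t")
            section_name, _, field_name = key.partition(".")
            section = getattr(cfg, section_name)
            current = getattr(section, field_name)
            setattr(section, field_name, _parse(text, current))
        return cfg


def _parse(text: str, like: Any) -> Any:
    if isinstance(like, bool):
        return text.strip().lower() in ("true", "1", "yes")
    if isinstance(like, tuple):
        return tuple(float(t) for t in text.split(","))
    if isinstance(like, int):
        return int(text)
    if isinstance(like, float):
        return float(text)
    return text.strip()
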