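"""Reading and writing subject sessions in inspectable plain-text formats.

A *session* is one subject's recording: four synchronized physiological
channels (ECG, electrodermal activity, respiration, trapezius EMG) sampled at
a common rate, a phase manifest (baseline, socioevaluative stressor "tsst",
scenarios 1-5), a baseline biomarker profile (salivary cortisol, state-anxiety
score) and per-scenario mission logs.

On disk a session is a directory::

    <subject_id>/
        subject.tsv       key-value: subject_id, group
        phases.tsv        phase <TAB> start_s <TAB> end_s
        ecg.csv           "#key: value" header (name, unit, sampling_rate),
        eda.csv           then one sample per line at fixed precision
        respiration.csv
        emg.csv
        profile.tsv       key-value baseline profile (optional)
        missions.tsv      one row per scenario mission log (optional)

Time is seconds from session start; phase intervals are half-open
``[start_s, end_s)`` and sample ``i`` covers ``[i/fs, (i+1)/fs)``, so the
samples of a phase are indices ``ceil(start*fs) .. ceil(end*fs) - 1``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

CHANNEL_NAMES = ("ecg", "eda", "respiration", "emg")
CHANNEL_UNITS = {"ecg": "mV", "eda": "uS", "respiration": "au", "emg": "mV"}
PHASE_NAMES = (
    "baseline", "tsst",
    "scenario1", "scenario2", "scenario3", "scenario4", "scenario5",
)
SCENARIO_PHASES = PHASE_NAMES[2:]
MIN_BASELINE_S = 300.0
SAMPLE_FMT = "%.6f"


class SessionIOError(ValueError):
    """Base class for session validation and parsing failures."""


class IncompleteSessionError(SessionIOError):
    """A required channel or file is missing: "incomplete session"."""


class InvalidManifestError(SessionIOError):
    """Phase manifest is malformed or inconsistent: "invalid manifest"."""


class UnitError(SessionIOError):
    """A channel declares an unexpected unit: "unit error"."""


@dataclass
class ChannelSignal:
    """One raw channel: named samples at a fixed sampling rate."""

    name: str
    samples: np.ndarray
    sampling_rate: float
    unit: str = ""

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise SessionIOError(f"unknown channel name {self.name!r}")
        if self.sampling_rate <= 0:
            raise SessionIOError("sampling_rate must be > 0")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise SessionIOError("channel samples must be one-dimensional")
        if self.samples.size < 2 * self.sampling_rate:
            raise SessionIOError(
                f"channel {self.name}: need at least 2 s of samples"
            )
        if not self.unit:
            self.unit = CHANNEL_UNITS[self.name]
        elif self.unit != CHANNEL_UNITS[self.name]:
            raise UnitError(
                f"unit error: channel {self.name} declares {self.unit!r}, "
                f"expected {CHANNEL_UNITS[self.name]!r}"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    def slice_window(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples whose coverage interval starts inside [start_s, end_s)."""
        fs = self.sampling_rate
        i0 = int(math.ceil(start_s * fs - 1e-9))
        i1 = int(math.ceil(end_s * fs - 1e-9))
        return self.samples[i0:i1]


@dataclass(frozen=True)
class PhaseAnnotation:
    """Half-open phase interval [start_s, end_s) in session time."""

    phase: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.phase not in PHASE_NAMES:
            raise InvalidManifestError(
                f"invalid manifest: unknown phase {self.phase!r}"
            )
        if not (0 <= self.start_s < self.end_s):
            raise InvalidManifestError(
                f"invalid manifest: phase {self.phase} has interval "
                f"[{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Recording:
    """One subject-session: synchronized channels plus phase annotations."""

    subject_id: str
    group: str
    channels: dict[str, ChannelSignal]
    phases: list[PhaseAnnotation]

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise SessionIOError("subject_id must be non-empty")
        if self.group not in ("control", "experimental"):
            raise SessionIOError(f"unknown group {self.group!r}")
        if not self.channels:
            raise IncompleteSessionError("incomplete session: no channels")
        rates = {c.sampling_rate for c in self.channels.values()}
        if len(rates) > 1:
            raise SessionIOError("channels must share one sampling rate")
        lengths = {c.samples.size for c in self.channels.values()}
        if len(lengths) > 1:
            raise SessionIOError("channels must have equal length")
        self._validate_phases()

    def _validate_phases(self) -> None:
        ordered = sorted(self.phases, key=lambda p: p.start_s)
        for a, b in zip(ordered, ordered[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise InvalidManifestError(
                    f"invalid manifest: phases {a.phase} and {b.phase} overlap"
                )
        names = [p.phase for p in self.phases]
        if len(names) != len(set(names)):
            raise InvalidManifestError("invalid manifest: duplicate phase")
        duration = self.duration_s
        for p in self.phases:
            if p.end_s > duration + 1e-9:
                raise InvalidManifestError(
                    f"invalid manifest: phase {p.phase} ends at {p.end_s} s "
                    f"but the signal lasts {duration:.3f} s"
                )
        base = self.get_phase("baseline")
        if base is None:
            logger.warning("%s: no baseline phase annotated", self.subject_id)
        elif base.duration_s < MIN_BASELINE_S:
            logger.warning(
                "%s: baseline phase is %.0f s (< %.0f s)",
                self.subject_id, base.duration_s, MIN_BASELINE_S,
            )

    @property
    def sampling_rate(self) -> float:
        return next(iter(self.channels.values())).sampling_rate

    @property
    def duration_s(self) -> float:
        return next(iter(self.channels.values())).duration_s

    def get_phase(self, name: str) -> PhaseAnnotation | None:
        for p in self.phases:
            if p.phase == name:
                return p
        return None


@dataclass
class BaselineProfile:
    """Pre-stressor biomarkers: salivary cortisol (ug/dl) and state-anxiety
    total (20-80), optionally with the 20 item responses (already keyed)."""

    subject_id: str
    cortisol_baseline: float
    stai_baseline: float
    cortisol_final: float | None = None
    stai_items: list[int] | None = None

    def __post_init__(self) -> None:
        if self.cortisol_baseline < 0:
            raise SessionIOError("cortisol must be >= 0")
        if self.cortisol_final is not None and self.cortisol_final < 0:
            raise SessionIOError("cortisol must be >= 0")
        if not (20 <= self.stai_baseline <= 80):
            raise SessionIOError("STAI total must lie in [20, 80]")
        if self.stai_items is not None:
            from .scoring import score_stai  # local import avoids a cycle
            total = score_stai(self.stai_items)
            if total != self.stai_baseline:
                raise SessionIOError(
                    f"STAI items sum to {total}, profile says "
                    f"{self.stai_baseline}"
                )


@dataclass(frozen=True)
class MissionLog:
    """Per-scenario mission outcome counts and timing."""

    subject_id: str
    scenario: int
    duration_s: float
    objectives_total: int
    objectives_met: int
    times_shot: int
    civilian_hits: int
    par_time_s: float

    def __post_init__(self) -> None:
        if not (1 <= self.scenario <= 5):
            raise SessionIOError("scenario must be 1-5")
        if not (0 <= self.objectives_met <= self.objectives_total):
            raise SessionIOError("objectives_met must be in [0, total]")
        if min(self.times_shot, self.civilian_hits) < 0:
            raise SessionIOError("counts must be >= 0")
        if self.duration_s < 0 or self.par_time_s <= 0:
            raise SessionIOError("durations must be positive")


# ---------------------------------------------------------------------------
# file I/O


def _write_keyvals(path: Path, pairs: Iterable[tuple[str, object]]) -> None:
    path.write_text("".join(f"{k}\t{v}\n" for k, v in pairs))


def _read_keyvals(path: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("\t")
        out[key] = val
    return out


def write_channel(path: Path, channel: ChannelSignal) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name: {channel.name}\n")
        fh.write(f"# unit: {channel.unit}\n")
        fh.write(f"# sampling_rate: {channel.sampling_rate:g}\n")
        np.savetxt(fh, channel.samples, fmt=SAMPLE_FMT)


def read_channel(path: Path) -> ChannelSignal:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            pos = fh.tell()
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
        samples = np.loadtxt(fh, dtype=float)
    for key in ("name", "unit", "sampling_rate"):
        if key not in meta:
            raise SessionIOError(f"{path}: channel header lacks {key!r}")
    return ChannelSignal(
        name=meta["name"],
        samples=np.atleast_1d(samples),
        sampling_rate=float(meta["sampling_rate"]),
        unit=meta["unit"],
    )


def _read_manifest(path: Path) -> list[PhaseAnnotation]:
    phases = []
    lines = path.read_text().splitlines()
    for line in lines[1:]:  # header row
        line = line.strip()
        if not line:
            continue
        name, start, end = line.split("\t")
        phases.append(PhaseAnnotation(name, float(start), float(end)))
    return phases


def _write_manifest(path: Path, phases: Sequence[PhaseAnnotation]) -> None:
    rows = ["phase\tstart_s\tend_s"]
    for p in sorted(phases, key=lambda p: p.start_s):
        rows.append(f"{p.phase}\t{p.start_s:g}\t{p.end_s:g}")
    path.write_text("\n".join(rows) + "\n")


def write_session(
    session_dir: str | Path,
    recording: Recording,
    profile: BaselineProfile | None = None,
    missions: Sequence[MissionLog] | None = None,
) -> Path:
    """Write one subject session; returns the session directory.

    The numeric round trip through :func:`read_session` is lossless at the
    declared precision (six decimals).
    """
    root = Path(session_dir)
    root.mkdir(parents=True, exist_ok=True)
    _write_keyvals(root / "subject.tsv", [
        ("subject_id", recording.subject_id), ("group", recording.group),
    ])
    _write_manifest(root / "phases.tsv", recording.phases)
    for name, channel in sorted(recording.channels.items()):
        write_channel(root / f"{name}.csv", channel)
    if recording.get_phase("baseline") is None:
        logger.warning(
            "%s: writing session without a baseline phase",
            recording.subject_id,
        )
    if profile is not None:
        pairs: list[tuple[str, object]] = [
            ("subject_id", profile.subject_id),
            ("cortisol_baseline", f"{profile.cortisol_baseline:.4f}"),
            ("stai_baseline", f"{profile.stai_baseline:g}"),
        ]
        if profile.cortisol_final is not None:
            pairs.append(("cortisol_final", f"{profile.cortisol_final:.4f}"))
        if profile.stai_items is not None:
            pairs.append(
                ("stai_items", ",".join(str(i) for i in profile.stai_items))
            )
        _write_keyvals(root / "profile.tsv", pairs)
    if missions:
        rows = ["subject_id\tscenario\tduration_s\tobjectives_total\t"
                "objectives_met\ttimes_shot\tcivilian_hits\tpar_time_s"]
        for m in sorted(missions, key=lambda m: m.scenario):
            rows.append(
                f"{m.subject_id}\t{m.scenario}\t{m.duration_s:.3f}\t"
                f"{m.objectives_total}\t{m.objectives_met}\t{m.times_shot}\t"
                f"{m.civilian_hits}\t{m.par_time_s:g}"
            )
        (root / "missions.tsv").write_text("\n".join(rows) + "\n")
    return root


def read_session(
    session_dir: str | Path,
    required_channels: Sequence[str] = ("ecg",),
) -> tuple[Recording, BaselineProfile | None, list[MissionLog]]:
    """Read and validate one subject session directory.

    Channels listed in ``required_channels`` must be present (default: ECG
    only); any other absent channel is tolerated with a warning so that e.g.
    a subject whose EDA electrode detached is still usable for the non-EDA
    features.
    """
    root = Path(session_dir)
    subject_path = root / "subject.tsv"
    manifest_path = root / "phases.tsv"
    if not subject_path.exists() or not manifest_path.exists():
        raise IncompleteSessionError(
            f"incomplete session: {root} lacks subject.tsv or phases.tsv"
        )
    meta = _read_keyvals(subject_path)
    channels: dict[str, ChannelSignal] = {}
    for name in CHANNEL_NAMES:
        path = root / f"{name}.csv"
        if path.exists():
            channels[name] = read_channel(path)
        elif name in required_channels:
            raise IncompleteSessionError(
                f"incomplete session: missing required channel {name!r}"
            )
        else:
            logger.warning("%s: channel %s missing", meta.get("subject_id"),
                           name)
    recording = Recording(
        subject_id=meta.get("subject_id", ""),
        group=meta.get("group", ""),
        channels=channels,
        phases=_read_manifest(manifest_path),
    )
    profile = None
    if (root / "profile.tsv").exists():
        pv = _read_keyvals(root / "profile.tsv")
        profile = BaselineProfile(
            subject_id=pv["subject_id"],
            cortisol_baseline=float(pv["cortisol_baseline"]),
            stai_baseline=float(pv["stai_baseline"]),
            cortisol_final=(
                float(pv["cortisol_final"]) if "cortisol_final" in pv else None
            ),
            stai_items=(
                [int(t) for t in pv["stai_items"].split(",")]
                if "stai_items" in pv else None
            ),
        )
    missions: list[MissionLog] = []
    if (root / "missions.tsv").exists():
        lines = (root / "missions.tsv").read_text().splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            sid, scen, dur, tot, met, shot, civ, par = line.split("\t")
            missions.append(MissionLog(
                subject_id=sid, scenario=int(scen), duration_s=float(dur),
                objectives_total=int(tot), objectives_met=int(met),
                times_shot=int(shot), civilian_hits=int(civ),
                par_time_s=float(par),
            ))
    return recording, profile, missions
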