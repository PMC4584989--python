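"""Synthetic cohort generation for end-to-end testing of the pipeline.

Emulates a two-group acute-stress study session: a seated baseline
recording, a 15-minute socioevaluative stressor (three 5-minute segments:
anticipation, speech, arithmetic), then five simulated mission scenarios.
Experimental subjects carry a latent resilience phenotype that sets how
their heart rate and skin conductance react to the stressor and how much of
that reaction persists through the scenarios; control subjects stay flat.
Baseline biomarkers (salivary cortisol, state-anxiety total) are drawn from
phenotype-conditioned truncated normals whose mixture matches the cohort
moments the analysis assumes (cortisol 0.38 +/- 0.28 ug/dl, anxiety
30 +/- 9), with the gradient that resistant subjects run high-cortisol /
low-anxiety and recovery subjects the reverse.

Every random draw flows from one seed through per-subject spawned
generators, so a config plus seed fully determines all outputs, file for
file.  Ground truth (phenotype and per-phase targets) is emitted alongside
each cohort and never read by the analysis pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .session_io import (
    BaselineProfile, ChannelSignal, MissionLog, PhaseAnnotation, Recording,
    PHASE_NAMES, SCENARIO_PHASES, write_session,
)

# cohort grand reference for the biomarker mixture (used when rescaling
# phenotype separation): cortisol in ug/dl, anxiety total
GRAND_CORTISOL = 0.38
GRAND_STAI = 31.0


@dataclass(frozen=True)
class PhenotypeSpec:
    """Latent reactivity profile and biomarker distribution of one class.

    ``*_reactivity_pct`` is the percent rise of the measure at the stressor
    relative to the subject's own baseline; ``*_residual_pct`` the percent
    elevation persisting through the scenarios.  Reactivities must be
    consistent with the class's defining rule at the default 5% threshold.
    """

    label: str
    hr_reactivity_pct: float
    hr_residual_pct: float
    scl_reactivity_pct: float
    scl_residual_pct: float
    cortisol_mean: float
    cortisol_sd: float
    stai_mean: float
    stai_sd: float

    def __post_init__(self) -> None:
        react = (self.hr_reactivity_pct + self.scl_reactivity_pct) / 2
        resid = (self.hr_residual_pct + self.scl_residual_pct) / 2
        ok = {
            "control": react <= 5,
            "resistant": react <= 5,
            "resilient": react > 5 and resid <= 5,
            "recovery": react > 5 and 5 < resid < react,
            "dysfunctional": react > 5 and resid > react,
        }
        if not ok.get(self.label, False):
            raise ValueError(
                f"phenotype {self.label!r}: reactivity {react}% / residual "
                f"{resid}% violates the class's defining rule"
            )


DEFAULT_PHENOTYPES: dict[str, PhenotypeSpec] = {
    "control": PhenotypeSpec("control", 1.0, 0.5, 1.0, 0.5,
                             GRAND_CORTISOL, 0.25, 30.0, 6.0),
    "resistant": PhenotypeSpec("resistant", 2.0, 1.0, 2.0, 1.0,
                               0.65, 0.20, 24.0, 4.0),
    "resilient": PhenotypeSpec("resilient", 25.0, 2.0, 25.0, 2.0,
                               0.38, 0.25, 30.0, 6.0),
    "recovery": PhenotypeSpec("recovery", 25.0, 12.0, 25.0, 12.0,
                              0.18, 0.10, 38.0, 5.0),
    "dysfunctional": PhenotypeSpec("dysfunctional", 25.0, 35.0, 25.0, 35.0,
                                   0.30, 0.15, 45.0, 6.0),
}


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one virtual cohort.

    Defaults mirror the emulated study: 20 controls and 19 experimental
    subjects, a 5-minute baseline, 15-minute stressor and five 10-minute
    scenarios at 500 Hz, and an experimental phenotype mix of 12/19
    resilient, 3/19 resistant and 4/19 recovery.
    """

    n_control: int = 20
    n_experimental: int = 19
    phenotype_mix: dict[str, float] = field(default_factory=lambda: {
        "resilient": 12 / 19, "resistant": 3 / 19, "recovery": 4 / 19,
    })
    sampling_rate: float = 500.0
    baseline_s: float = 300.0
    tsst_s: float = 900.0
    scenario_s: float = 600.0
    # baseline physiology (subject-level draws)
    hr_base_mean: float = 70.0
    hr_base_sd: float = 5.0
    scl_base_mean: float = 4.0
    scl_base_sd: float = 1.0
    # within-subject phase-to-phase variability of the latent targets, in
    # percent of the target; noise_scale multiplies every noise term at once
    phase_target_noise_pct: float = 1.0
    rr_jitter_ms: float = 30.0
    rsa_amplitude_bpm: float = 6.0
    resp_rate_bpm: float = 15.0
    ecg_noise_mV: float = 0.03
    eda_noise_uS: float = 0.005
    scr_amplitude_uS: float = 0.3
    scr_rate_base_per_min: float = 3.0
    scr_rate_stress_per_min: float = 6.0
    emg_rms_mV: float = 0.02
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.phenotype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"phenotype mix proportions sum to {total}, expected 1"
            )
        unknown = set(self.phenotype_mix) - set(DEFAULT_PHENOTYPES)
        if unknown:
            raise ValueError(f"unknown phenotypes in mix: {sorted(unknown)}")

    @property
    def phase_durations(self) -> dict[str, float]:
        out = {"baseline": self.baseline_s, "tsst": self.tsst_s}
        out.update({p: self.scenario_s for p in SCENARIO_PHASES})
        return out

    def phase_annotations(self) -> list[PhaseAnnotation]:
        phases, t = [], 0.0
        for name in PHASE_NAMES:
            d = self.phase_durations[name]
            phases.append(PhaseAnnotation(name, t, t + d))
            t += d
        return phases

    @property
    def total_duration_s(self) -> float:
        return sum(self.phase_durations.values())


# ---------------------------------------------------------------------------
# channel synthesizers


def synth_beat_times(hr_by_phase: dict[str, float],
                     durations: dict[str, float],
                     rsa_amplitude_bpm: float, resp_rate_bpm: float,
                     rr_jitter_s: float, rng: np.random.Generator
                     ) -> np.ndarray:
    """Beat times whose instantaneous rate tracks the per-phase target with
    sinusoidal respiratory modulation and Gaussian R-R jitter."""
    edges, t = [], 0.0
    for name in durations:
        edges.append((t, t + durations[name], hr_by_phase[name]))
        t += durations[name]
    total = t
    f_resp = resp_rate_bpm / 60.0
    times = []
    t = 0.2
    while t < total:
        hr = next(h for lo, hi, h in edges if lo <= t < hi)
        hr += (rsa_amplitude_bpm / 2.0) * np.sin(2 * np.pi * f_resp * t)
        rr = 60.0 / hr
        if rr_jitter_s > 0:
            rr += rng.normal(0.0, rr_jitter_s)
        times.append(t)
        t += max(rr, 0.25)
    return np.asarray(times)


def render_ecg(beat_times: np.ndarray, duration_s: float, fs: float,
               noise_mV: float, rng: np.random.Generator) -> ChannelSignal:
    """Render a beat train as template R waves (Gaussian, 1 mV, sigma 8 ms)
    on additive Gaussian noise at 500 Hz or any other rate."""
    n = int(round(duration_s * fs))
    x = (rng.normal(0.0, noise_mV, n) if noise_mV > 0
         else np.zeros(n))
    sigma = 0.008
    half = int(round(4 * sigma * fs))
    tpl = np.exp(-0.5 * ((np.arange(-half, half + 1) / fs) / sigma) ** 2)
    for bt in beat_times:
        c = int(round(bt * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        x[lo:hi] += tpl[lo - (c - half): hi - (c - half)]
    return ChannelSignal("ecg", x, fs)


def synth_ecg(hr_by_phase: dict[str, float], durations: dict[str, float],
              rsa_amplitude_bpm: float, resp_rate_bpm: float,
              rr_jitter_s: float, noise_mV: float,
              fs: float, rng: np.random.Generator) -> ChannelSignal:
    beats = synth_beat_times(hr_by_phase, durations, rsa_amplitude_bpm,
                             resp_rate_bpm, rr_jitter_s, rng)
    return render_ecg(beats, sum(durations.values()), fs, noise_mV, rng)


def _scr_kernel(fs: float, rise_s: float = 1.0, decay_s: float = 4.0
                ) -> np.ndarray:
    t = np.arange(0, int(round(8 * decay_s * fs))) / fs
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


def _event_times(rate_per_min: float, start: float, duration: float,
                 rng: np.random.Generator, min_gap_s: float = 2.0
                 ) -> np.ndarray:
    """Uniform (Poisson-conditioned) event times realizing the configured
    rate exactly, with a minimum separation."""
    n = int(round(rate_per_min * duration / 60.0))
    if n <= 0:
        return np.empty(0)
    for _ in range(200):
        t = np.sort(rng.uniform(start, start + duration - 5.0, n))
        if n == 1 or np.min(np.diff(t)) >= min_gap_s:
            return t
    # fall back to jittered regular spacing when the window is crowded
    grid = start + (np.arange(n) + 0.5) * (duration - 5.0) / n
    return grid + rng.uniform(-0.5, 0.5, n)


def synth_eda(scl_by_phase: dict[str, float],
              scr_rate_by_phase: dict[str, float],
              durations: dict[str, float], scr_amplitude_uS: float,
              noise_uS: float, fs: float, rng: np.random.Generator
              ) -> ChannelSignal:
    """Tonic level steps (smoothed) + slow drift + discrete skin-conductance
    responses with a 1 s rise / 4 s decay kernel."""
    total = sum(durations.values())
    n = int(round(total * fs))
    tonic = np.empty(n)
    t0 = 0.0
    events: list[float] = []
    for name in durations:
        d = durations[name]
        i0, i1 = int(round(t0 * fs)), int(round((t0 + d) * fs))
        tonic[i0:i1] = scl_by_phase[name]
        events.extend(_event_times(scr_rate_by_phase[name], t0, d, rng))
        t0 += d
    # two passes of a 20 s boxcar smooth the phase steps without moving the
    # within-phase mean appreciably
    width = max(1, int(round(20 * fs)))
    tonic = uniform_filter1d(uniform_filter1d(tonic, width), width)
    x = tonic
    if noise_uS > 0:
        tt = np.arange(n) / fs
        x = x + 0.1 * noise_uS / 0.005 * np.sin(2 * np.pi * 0.01 * tt)
        x = x + rng.normal(0.0, noise_uS, n)
    kernel = _scr_kernel(fs)
    klen = kernel.size
    x = np.array(x, dtype=float)
    for et in events:
        c = int(round(et * fs))
        hi = min(n, c + klen)
        x[c:hi] += scr_amplitude_uS * kernel[: hi - c]
    return ChannelSignal("eda", np.clip(x, 0.0, None), fs)


def synth_respiration(rate_by_phase: dict[str, float],
                      durations: dict[str, float], fs: float,
                      noise: float, rng: np.random.Generator
                      ) -> ChannelSignal:
    """Thoracic-expansion surrogate: unit sinusoid with phase-continuous
    frequency following the per-phase breathing rate."""
    total = sum(durations.values())
    n = int(round(total * fs))
    freq = np.empty(n)
    t0 = 0.0
    for name in durations:
        d = durations[name]
        freq[int(round(t0 * fs)): int(round((t0 + d) * fs))] = (
            rate_by_phase[name] / 60.0
        )
        t0 += d
    phase = 2 * np.pi * np.cumsum(freq) / fs
    x = np.sin(phase)
    if noise > 0:
        x = x + rng.normal(0.0, noise, n)
    return ChannelSignal("respiration", x, fs)


def synth_emg(rms_by_phase: dict[str, float], durations: dict[str, float],
              fs: float, rng: np.random.Generator) -> ChannelSignal:
    """Surface-EMG surrogate: zero-mean Gaussian noise whose SD equals the
    per-phase target RMS."""
    total = sum(durations.values())
    n = int(round(total * fs))
    x = np.empty(n)
    t0 = 0.0
    for name in durations:
        d = durations[name]
        i0, i1 = int(round(t0 * fs)), int(round((t0 + d) * fs))
        x[i0:i1] = rng.normal(0.0, rms_by_phase[name], i1 - i0)
        t0 += d
    return ChannelSignal("emg", x, fs)


# ---------------------------------------------------------------------------
# biomarker profiles


def synth_baseline_profile(subject_id: str, phenotype: PhenotypeSpec,
                           rng: np.random.Generator,
                           separation: float = 1.0,
                           spread: float = 1.0) -> BaselineProfile:
    """Draw a biomarker profile conditioned on the phenotype.

    ``separation`` scales how far the phenotype's means sit from the cohort
    grand reference (1 = the calibrated mixture; larger = easier classes);
    ``spread`` scales the within-class SDs.
    """
    c_mean = GRAND_CORTISOL + separation * (phenotype.cortisol_mean
                                            - GRAND_CORTISOL)
    s_mean = GRAND_STAI + separation * (phenotype.stai_mean - GRAND_STAI)
    cortisol = float(np.clip(
        rng.normal(c_mean, phenotype.cortisol_sd * spread), 0.02, None))
    stai = int(np.clip(
        round(rng.normal(s_mean, phenotype.stai_sd * spread)), 20, 80))
    final = float(np.clip(cortisol * rng.normal(0.32, 0.08), 0.02, None))
    # pre-keyed items summing to the total: start at 1, sprinkle the excess
    items = np.ones(20, dtype=int)
    for _ in range(stai - 20):
        open_idx = np.flatnonzero(items < 4)
        items[rng.choice(open_idx)] += 1
    return BaselineProfile(
        subject_id=subject_id, cortisol_baseline=cortisol,
        stai_baseline=stai, cortisol_final=final,
        stai_items=items.tolist(),
    )


def synth_profile_cohort(labels: list[str], seed: int,
                         separation: float = 1.0, spread: float = 1.0
                         ) -> pd.DataFrame:
    """Biomarker profiles (no raw signals) for a list of phenotype labels —
    the classifier-geometry test bed."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, label in enumerate(labels):
        p = synth_baseline_profile(f"S{i:03d}", DEFAULT_PHENOTYPES[label],
                                   rng, separation, spread)
        rows.append({"subject_id": p.subject_id, "label": label,
                     "cortisol_baseline": p.cortisol_baseline,
                     "stai_baseline": p.stai_baseline})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-cohort generation


def _phase_targets(base: float, reactivity_pct: float, residual_pct: float,
                   noise_pct: float, rng: np.random.Generator
                   ) -> dict[str, float]:
    mult = {"baseline": 1.0, "tsst": 1.0 + reactivity_pct / 100.0}
    mult.update({p: 1.0 + residual_pct / 100.0 for p in SCENARIO_PHASES})
    out = {}
    for name, m in mult.items():
        jitter = rng.normal(0.0, noise_pct / 100.0) if noise_pct > 0 else 0.0
        out[name] = base * m * (1.0 + jitter)
    return out


def generate_subject(subject_id: str, group: str, phenotype: PhenotypeSpec,
                     config: SyntheticCohortConfig,
                     rng: np.random.Generator
                     ) -> tuple[Recording, BaselineProfile,
                                list[MissionLog], dict]:
    """One subject-session with its ground-truth row."""
    ns = config.noise_scale
    durations = config.phase_durations
    hr0 = float(np.clip(rng.normal(config.hr_base_mean, config.hr_base_sd),
                        55.0, 95.0))
    scl0 = float(np.clip(rng.normal(config.scl_base_mean,
                                    config.scl_base_sd), 1.5, 8.0))
    noise_pct = config.phase_target_noise_pct * ns
    hr_t = _phase_targets(hr0, phenotype.hr_reactivity_pct,
                          phenotype.hr_residual_pct, noise_pct, rng)
    scl_t = _phase_targets(scl0, phenotype.scl_reactivity_pct,
                           phenotype.scl_residual_pct, noise_pct, rng)
    stress_mult = {p: (hr_t[p] / hr0 - 1.0) / max(
        phenotype.hr_reactivity_pct / 100.0, 1e-6) for p in PHASE_NAMES}
    scr_t = {p: config.scr_rate_base_per_min
             + (config.scr_rate_stress_per_min
                - config.scr_rate_base_per_min) * min(1.0, max(0.0,
                                                     stress_mult[p]))
             for p in PHASE_NAMES}
    resp_t = {p: config.resp_rate_bpm * (1.02 if p != "baseline" else 1.0)
              for p in PHASE_NAMES}
    emg_t = {p: config.emg_rms_mV * (1.1 if p.startswith("scenario")
                                     else 1.0) for p in PHASE_NAMES}

    fs = config.sampling_rate
    channels = {
        "ecg": synth_ecg(hr_t, durations, config.rsa_amplitude_bpm,
                         config.resp_rate_bpm,
                         config.rr_jitter_ms / 1000.0 * ns,
                         config.ecg_noise_mV * ns, fs, rng),
        "eda": synth_eda(scl_t, scr_t, durations, config.scr_amplitude_uS,
                         config.eda_noise_uS * ns, fs, rng),
        "respiration": synth_respiration(resp_t, durations, fs,
                                         0.05 * ns, rng),
        "emg": synth_emg(emg_t, durations, fs, rng),
    }
    recording = Recording(subject_id=subject_id, group=group,
                          channels=channels,
                          phases=config.phase_annotations())
    profile = synth_baseline_profile(subject_id, phenotype, rng)
    missions = []
    for s in range(1, 6):
        par = durations[f"scenario{s}"]
        p_hit = float(np.clip(0.95 - 0.08 * (s - 1), 0.4, 1.0))
        missions.append(MissionLog(
            subject_id=subject_id, scenario=s,
            duration_s=round(float(par * rng.uniform(0.75, 1.1)), 3),
            objectives_total=5,
            objectives_met=int(rng.binomial(5, p_hit)),
            times_shot=int(rng.poisson(0.4 * s)),
            civilian_hits=int(rng.poisson(0.05)),
            par_time_s=float(par),
        ))
    truth = {"subject_id": subject_id, "group": group,
             "phenotype": phenotype.label,
             "cortisol_baseline": profile.cortisol_baseline,
             "stai_baseline": profile.stai_baseline,
             "rsa_amplitude_bpm": config.rsa_amplitude_bpm}
    truth.update({f"true_hr_{p}": hr_t[p] for p in PHASE_NAMES})
    truth.update({f"true_scl_{p}": scl_t[p] for p in PHASE_NAMES})
    truth.update({f"true_edr_{p}": scr_t[p] for p in PHASE_NAMES})
    return recording, profile, missions, truth


def assign_phenotypes(config: SyntheticCohortConfig,
                      rng: np.random.Generator) -> list[str]:
    """Multinomial draw of experimental phenotype labels from the mix."""
    names = sorted(config.phenotype_mix)
    probs = [config.phenotype_mix[n] for n in names]
    counts = rng.multinomial(config.n_experimental, probs)
    labels = [n for n, c in zip(names, counts) for _ in range(c)]
    rng.shuffle(labels)
    return labels


def iter_cohort(config: SyntheticCohortConfig
                ) -> Iterator[tuple[Recording, BaselineProfile,
                                    list[MissionLog], dict]]:
    """Yield subjects one at a time (sessions are large; avoid holding a
    whole cohort in memory)."""
    root = np.random.default_rng(config.seed)
    labels = assign_phenotypes(config, root)
    n_total = config.n_control + config.n_experimental
    seeds = np.random.SeedSequence(config.seed).spawn(n_total)
    idx = 0
    for i in range(config.n_control):
        rng = np.random.default_rng(seeds[idx]); idx += 1
        yield generate_subject(f"C{i:03d}", "control",
                               DEFAULT_PHENOTYPES["control"], config, rng)
    for i in range(config.n_experimental):
        rng = np.random.default_rng(seeds[idx]); idx += 1
        yield generate_subject(f"E{i:03d}", "experimental",
                               DEFAULT_PHENOTYPES[labels[i]], config, rng)


def generate_cohort(config: SyntheticCohortConfig,
                    out_dir: str | Path) -> pd.DataFrame:
    """Write a full cohort of sessions under ``out_dir`` and return the
    ground-truth table (also written as ``ground_truth.tsv``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truths = []
    for recording, profile, missions, truth in iter_cohort(config):
        write_session(out / recording.subject_id, recording, profile,
                      missions)
        truths.append(truth)
    gt = pd.DataFrame(truths)
    gt.to_csv(out / "ground_truth.tsv", sep="\t", index=False,
              float_format="%.6f")
    lines = []
    for f in dataclasses.fields(config):
        val = getattr(config, f.name)
        if isinstance(val, dict):
            val = ",".join(f"{k}:{v}" for k, v in sorted(val.items()))
        lines.append(f"{f.name}\t{val}")
    (out / "cohort_config.tsv").write_text("\n".join(lines) + "\n")
    return gt
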