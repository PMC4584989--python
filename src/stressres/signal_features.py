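"""Per-phase autonomic feature extraction from raw channels.

Implements the study's feature set: mean heart rate and SDNN from the ECG
R-R series (intervals outside 40-180 bpm excluded), frequency-domain heart
rate variability (LF 0.04-0.15 Hz, HF 0.15-0.4 Hz) from the evenly resampled
R-R tachogram, peak-valley respiratory sinus arrhythmia, respiration rate
from strap zero-crossings, tonic skin conductance level, electrodermal
response rate from the 0.05-1 Hz phasic component with a 0.05 uS onset
threshold, and block-averaged trapezius EMG RMS.

All window arguments are half-open ``(start_s, end_s)`` intervals in session
time.  Features that cannot be computed (too few beats, flat signal) are
returned as NaN and logged, never raised, except where a precondition is
structurally violated (e.g. an undetectable ECG rhythm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import FeatureConfig
from .session_io import ChannelSignal, Recording

logger = logging.getLogger(__name__)

Window = tuple[float, float]

FEATURE_COLUMNS = [
    "hr_bpm", "sdnn_ms", "lf_power", "hf_power", "lf_hf_ratio",
    "rsa_bpm", "resp_rate_bpm", "scl_uS", "edr_per_min", "emg_rms_mV",
]


class UndetectableRhythmError(ValueError):
    """ECG carries no detectable rhythm (flat or all-NaN)."""


@dataclass
class BeatSeries:
    """Detected R-peak times with derived R-R intervals.

    ``rr_valid_mask[i]`` is False exactly where the instantaneous rate
    ``60 / rr_intervals_s[i]`` falls outside the configured 40-180 bpm band.
    """

    r_peak_times_s: np.ndarray
    rr_intervals_s: np.ndarray = field(init=False)
    rr_valid_mask: np.ndarray = field(init=False)
    bpm_limits: tuple[float, float] = (40.0, 180.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.r_peak_times_s, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("R-peak times must be strictly increasing")
        self.r_peak_times_s = t
        self.rr_intervals_s = np.diff(t)
        with np.errstate(divide="ignore"):
            bpm = 60.0 / self.rr_intervals_s
        lo, hi = self.bpm_limits
        self.rr_valid_mask = (bpm >= lo) & (bpm <= hi)

    def window_intervals(self, window: Window) -> tuple[np.ndarray, np.ndarray]:
        """(rr, valid_mask) of intervals lying fully inside the window."""
        start, end = window
        t = self.r_peak_times_s
        inside = (t[:-1] >= start) & (t[1:] < end)
        return self.rr_intervals_s[inside], self.rr_valid_mask[inside]


@dataclass
class RespCycleSeries:
    """Respiratory cycle boundaries (inspiration onsets) and mean rate."""

    cycle_boundaries_s: np.ndarray
    rate_breaths_per_min: float


@dataclass
class EDRSeries:
    """Electrodermal responses in a window: event onsets, per-minute rate,
    and the tonic skin conductance level."""

    event_times_s: np.ndarray
    rate_per_min: float
    scl_tonic_uS: float


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float],
              order: int) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(band[1], nyq * 0.99)
    sos = sps.butter(order, [band[0] / nyq, hi / nyq], btype="band",
                     output="sos")
    # pad by a few periods of the low corner; the default padding is far
    # too short for sub-0.1 Hz corners and leaves long edge transients
    padlen = min(x.size - 1, int(3 * fs / band[0]))
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def _lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 4
             ) -> np.ndarray:
    sos = sps.butter(order, cutoff / (fs / 2.0), btype="low", output="sos")
    padlen = min(x.size - 1, int(3 * fs / cutoff))
    return sps.sosfiltfilt(sos, x, padlen=padlen)


# ---------------------------------------------------------------------------
# ECG


def detect_r_peaks(ecg: ChannelSignal, config: FeatureConfig | None = None
                   ) -> BeatSeries:
    """Detect R peaks with a band-pass + squared-derivative energy detector.

    The ECG is band-passed to the QRS band, differentiated, squared and
    integrated over a 150 ms moving window; peaks of the energy envelope
    above an adaptive threshold mark beats, each refined to the local raw
    maximum so peak times land within one sample of the true R wave on clean
    signals.
    """
    config = config or FeatureConfig()
    x = np.asarray(ecg.samples, dtype=float)
    fs = ecg.sampling_rate
    if x.size < 10 * fs:
        raise ValueError("need at least 10 s of ECG")
    finite = np.isfinite(x)
    if not finite.any() or np.ptp(x[finite]) < 1e-9:
        raise UndetectableRhythmError("undetectable rhythm")
    x = np.where(finite, x, 0.0)

    bp = _bandpass(x, fs, config.ecg_band_hz, config.ecg_filter_order)
    energy = np.gradient(bp) ** 2
    win = max(1, int(round(0.150 * fs)))
    envelope = np.convolve(energy, np.ones(win) / win, mode="same")

    # adaptive threshold: a fraction of the envelope's upper quantile,
    # floored by its median so isolated noise bursts do not dominate
    q95 = np.quantile(envelope, 0.95)
    thresh = max(0.2 * q95, 2.0 * np.median(envelope))
    min_dist = max(1, int(round(60.0 / config.rr_valid_bpm[1] * fs * 0.8)))
    peaks, _ = sps.find_peaks(envelope, height=thresh, distance=min_dist)
    if peaks.size < 2:
        raise UndetectableRhythmError("undetectable rhythm")

    # refine each detection to the raw-signal maximum within +/-50 ms
    half = int(round(0.050 * fs))
    refined = np.empty(peaks.size, dtype=int)
    for i, p in enumerate(peaks):
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        refined[i] = lo + int(np.argmax(x[lo:hi]))
    refined = np.unique(refined)
    return BeatSeries(refined / fs, bpm_limits=config.rr_valid_bpm)


def mean_heart_rate(beats: BeatSeries, window: Window) -> float:
    """Mean heart rate in bpm: 60 / mean(valid R-R) over the window."""
    rr, valid = beats.window_intervals(window)
    rr = rr[valid]
    if rr.size < 2:
        logger.info("mean_heart_rate: <2 valid R-R intervals in %s", window)
        return float("nan")
    return 60.0 / float(np.mean(rr))


def sdnn(beats: BeatSeries, window: Window,
         config: FeatureConfig | None = None) -> float:
    """SDNN in ms: population SD of the valid R-R intervals in the window.

    Intended for windows of at least five minutes; shorter windows are
    computed anyway with a warning.
    """
    config = config or FeatureConfig()
    if window[1] - window[0] < config.sdnn_min_window_s:
        logger.warning("sdnn: window %.0f s < %.0f s (short_window)",
                       window[1] - window[0], config.sdnn_min_window_s)
    rr, valid = beats.window_intervals(window)
    rr = rr[valid]
    if rr.size < 2:
        return float("nan")
    return float(np.std(rr, ddof=config.sdnn_ddof) * 1000.0)


def hrv_spectrum(beats: BeatSeries, window: Window,
                 config: FeatureConfig | None = None
                 ) -> tuple[float, float, float]:
    """LF and HF band powers of the R-R tachogram, and their ratio.

    The valid R-R series is interpolated onto an even grid (4 Hz default),
    linearly detrended, and a Welch periodogram (64 s segments, 50% overlap)
    is integrated over the LF and HF bands by the rectangle rule.
    Returns ``(lf_power, hf_power, lf_hf_ratio)``; the ratio is NaN when the
    HF power is zero.
    """
    config = config or FeatureConfig()
    start, end = window
    if end - start < 120:
        logger.warning("hrv_spectrum: window %.0f s < 120 s", end - start)
    t = beats.r_peak_times_s
    inside = (t[:-1] >= start) & (t[1:] < end)
    sel = inside & beats.rr_valid_mask
    t_rr = t[1:][sel]           # each interval timestamped at its end beat
    rr = beats.rr_intervals_s[sel]
    if rr.size < 4 or t_rr[-1] - t_rr[0] < 10:
        return float("nan"), float("nan"), float("nan")

    fs_r = config.hrv_resample_hz
    grid = np.arange(t_rr[0], t_rr[-1], 1.0 / fs_r)
    tach = np.interp(grid, t_rr, rr)
    tach = sps.detrend(tach, type="linear")
    nperseg = min(tach.size, int(config.hrv_segment_s * fs_r))
    freqs, psd = sps.welch(tach, fs=fs_r, nperseg=nperseg,
                           noverlap=int(nperseg * config.hrv_overlap))
    df = freqs[1] - freqs[0]
    lf_lo, lf_hi = config.lf_band_hz
    hf_lo, hf_hi = config.hf_band_hz
    lf = float(np.sum(psd[(freqs >= lf_lo) & (freqs < lf_hi)]) * df)
    hf = float(np.sum(psd[(freqs >= hf_lo) & (freqs <= hf_hi)]) * df)
    ratio = lf / hf if hf > 1e-12 else float("nan")
    return lf, hf, ratio


# ---------------------------------------------------------------------------
# respiration


def respiratory_cycles(resp: ChannelSignal, window: Window,
                       config: FeatureConfig | None = None
                       ) -> RespCycleSeries | None:
    """Respiratory cycles from rising zero-crossings of the band-passed
    strap signal; boundaries mark inspiration onsets.

    Returns None when no full cycle is detectable (e.g. a flat strap).
    """
    config = config or FeatureConfig()
    start, end = window
    x = resp.slice_window(start, end)
    fs = resp.sampling_rate
    if x.size < 10 * fs or np.ptp(x) < 1e-9:
        return None
    filt = _bandpass(x, fs, config.resp_band_hz, config.resp_filter_order)
    if np.ptp(filt) < 1e-6:
        return None
    rising = np.flatnonzero((filt[:-1] < 0) & (filt[1:] >= 0))
    if rising.size < 2:
        return None
    # linear interpolation of the crossing instant between samples
    frac = -filt[rising] / (filt[rising + 1] - filt[rising])
    times = start + (rising + frac) / fs
    n_cycles = times.size - 1
    rate = n_cycles / ((times[-1] - times[0]) / 60.0)
    return RespCycleSeries(cycle_boundaries_s=times,
                           rate_breaths_per_min=float(rate))


def rsa_peak_valley(beats: BeatSeries, cycles: RespCycleSeries | None
                    ) -> float:
    """Peak-valley respiratory sinus arrhythmia in bpm.

    For each respiratory cycle, the difference between the maximum and the
    minimum instantaneous heart rate (stepwise 60/RR, one value per beat
    whose R peak falls in the cycle) is taken; the RSA is the mean of those
    ranges over cycles holding at least two beats.  At least three such
    cycles are required, otherwise NaN.
    """
    if cycles is None or cycles.cycle_boundaries_s.size < 2:
        return float("nan")
    t = beats.r_peak_times_s[:-1]       # beat starting each interval
    hr = 60.0 / beats.rr_intervals_s
    t, hr = t[beats.rr_valid_mask], hr[beats.rr_valid_mask]
    ranges = []
    bounds = cycles.cycle_boundaries_s
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        in_cycle = hr[(t >= lo) & (t < hi)]
        if in_cycle.size >= 2:
            ranges.append(np.max(in_cycle) - np.min(in_cycle))
    if len(ranges) < 3:
        logger.info("rsa_peak_valley: <3 qualifying cycles")
        return float("nan")
    return float(np.mean(ranges))


# ---------------------------------------------------------------------------
# electrodermal activity


def detect_edr(eda: ChannelSignal, window: Window,
               config: FeatureConfig | None = None) -> EDRSeries:
    """Count electrodermal responses and measure tonic level in a window.

    The channel is band-passed to the phasic band (0.05-1 Hz); an EDR event
    opens at an upward crossing of the onset threshold (0.05 uS) and closes
    when the signal falls back below threshold minus the hysteresis band
    (0.001 uS).  A refractory second after each onset suppresses
    double-counted ripple.  The tonic skin conductance level is the mean of
    the low-passed (< 0.05 Hz) raw signal over the window.
    """
    config = config or FeatureConfig()
    start, end = window
    x = eda.slice_window(start, end)
    fs = eda.sampling_rate
    minutes = (end - start) / 60.0
    if x.size < 30 * fs:
        logger.warning("detect_edr: window %.0f s is short", end - start)
    if np.ptp(x) < 1e-9:
        logger.warning("detect_edr: flat or saturated EDA; rate set to 0")
        return EDRSeries(np.empty(0), 0.0, float(np.mean(x)))

    # decimate by block mean to ~20 Hz before filtering: the phasic band
    # tops out at 1 Hz, and pushing a 0.05 Hz corner through a filter
    # designed at 500 Hz is numerically ill-conditioned
    q = max(1, int(fs // 20))
    if q > 1:
        n_blocks = x.size // q
        x = x[: n_blocks * q].reshape(n_blocks, q).mean(axis=1)
        fs = fs / q
    phasic = _bandpass(x, fs, config.eda_phasic_band_hz,
                       config.eda_filter_order)
    onset = config.edr_onset_uS
    close = onset - config.edr_hysteresis_uS
    refractory = int(round(config.edr_refractory_s * fs))

    above = phasic >= onset
    below = phasic < close
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
    closing = np.flatnonzero(~below[:-1] & below[1:]) + 1
    marks = sorted([(i, "open") for i in rising]
                   + [(i, "close") for i in closing])
    events = []
    open_event = False
    last_onset = -refractory
    for idx, kind in marks:
        if kind == "open" and not open_event:
            if idx - last_onset >= refractory:
                events.append(idx)
                last_onset = idx
                open_event = True
        elif kind == "close" and open_event:
            open_event = False

    tonic = _lowpass(x, fs, config.scl_lowpass_hz)
    return EDRSeries(
        event_times_s=start + np.asarray(events, dtype=float) / fs,
        rate_per_min=len(events) / minutes,
        scl_tonic_uS=float(np.mean(tonic)),
    )


# ---------------------------------------------------------------------------
# EMG


def emg_rms(emg: ChannelSignal, window: Window,
            config: FeatureConfig | None = None) -> float:
    """Block-averaged EMG RMS: RMS over non-overlapping 100-sample blocks
    (200 ms at 500 Hz), averaged across the window."""
    config = config or FeatureConfig()
    x = emg.slice_window(*window)
    block = config.emg_block_samples
    if x.size < block:
        return float("nan")
    n_blocks = x.size // block
    blocks = x[: n_blocks * block].reshape(n_blocks, block)
    return float(np.mean(np.sqrt(np.mean(blocks ** 2, axis=1))))


# ---------------------------------------------------------------------------
# orchestration


def extract_features(recording: Recording,
                     config: FeatureConfig | None = None) -> pd.DataFrame:
    """One feature vector per annotated phase of a recording.

    Returns a DataFrame with columns ``subject_id, group, phase`` plus
    :data:`FEATURE_COLUMNS`; features whose channel is absent or whose
    inputs are insufficient come back NaN (logged, not fatal).
    """
    config = config or FeatureConfig()
    beats: BeatSeries | None = None
    if "ecg" in recording.channels:
        try:
            beats = detect_r_peaks(recording.channels["ecg"], config)
        except (UndetectableRhythmError, ValueError) as exc:
            logger.warning("%s: R-peak detection failed: %s",
                           recording.subject_id, exc)

    rows = []
    for phase in sorted(recording.phases, key=lambda p: p.start_s):
        window = (phase.start_s, phase.end_s)
        row: dict[str, object] = {
            "subject_id": recording.subject_id,
            "group": recording.group,
            "phase": phase.phase,
        }
        row.update({c: float("nan") for c in FEATURE_COLUMNS})
        if beats is not None:
            row["hr_bpm"] = mean_heart_rate(beats, window)
            row["sdnn_ms"] = sdnn(beats, window, config)
            lf, hf, ratio = hrv_spectrum(beats, window, config)
            row.update(lf_power=lf, hf_power=hf, lf_hf_ratio=ratio)
        cycles = None
        if "respiration" in recording.channels:
            cycles = respiratory_cycles(recording.channels["respiration"],
                                        window, config)
            if cycles is not None:
                row["resp_rate_bpm"] = cycles.rate_breaths_per_min
        if beats is not None and cycles is not None:
            row["rsa_bpm"] = rsa_peak_valley(beats, cycles)
        if "eda" in recording.channels:
            edr = detect_edr(recording.channels["eda"], window, config)
            row["scl_uS"] = edr.scl_tonic_uS
            row["edr_per_min"] = edr.rate_per_min
        if "emg" in recording.channels:
            row["emg_rms_mV"] = emg_rms(recording.channels["emg"], window,
                                        config)
        rows.append(row)
    return pd.DataFrame(rows,
                        columns=["subject_id", "group", "phase"]
                        + FEATURE_COLUMNS)
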