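import numpy as np
import pytest

from stressres import signal_features as sf
from stressres import synthetic as syn
from stressres.session_io import ChannelSignal

FS = 500.0


def _ecg_from_beats(beat_times, duration, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    return syn.render_ecg(np.asarray(beat_times), duration, FS, noise, rng)


def _brute_force_peaks(ecg: ChannelSignal, height=0.5):
    """Oracle: direct per-sample local-maximum scan, no filtering."""
    x, out = ecg.samples, []
    for i in range(1, x.size - 1):
        if x[i] >= height and x[i] >= x[i - 1] and x[i] > x[i + 1]:
            out.append(i / ecg.sampling_rate)
    return np.array(out)


# ---------------------------------------------------------------------------
# R peaks


def test_r_peaks_recover_60_bpm_train():
    beats_true = np.arange(0.5, 60.0, 1.0)
    ecg = _ecg_from_beats(beats_true, 60.0)
    beats = sf.detect_r_peaks(ecg)
    assert abs(beats.r_peak_times_s.size - 60) <= 1
    rr = beats.rr_intervals_s
    np.testing.assert_allclose(rr, 1.0, atol=0.004)
    # within one sample of the rendered maxima
    oracle = _brute_force_peaks(ecg)
    matched = np.array([oracle[np.argmin(np.abs(oracle - t))]
                        for t in beats.r_peak_times_s])
    assert np.max(np.abs(matched - beats.r_peak_times_s)) <= 1.0 / FS


def test_out_of_band_interval_masked_invalid():
    # one 2.0 s pause (30 bpm) inside a 60 bpm train
    t = np.concatenate([np.arange(0.5, 30.0, 1.0),
                        np.arange(31.5, 60.0, 1.0)])
    ecg = _ecg_from_beats(t, 60.0)
    beats = sf.detect_r_peaks(ecg)
    invalid = ~beats.rr_valid_mask
    assert invalid.sum() == 1
    assert beats.rr_intervals_s[invalid][0] == pytest.approx(2.0, abs=0.01)


def test_flat_signal_has_no_rhythm():
    flat = ChannelSignal("ecg", np.full(int(30 * FS), 0.7), FS)
    with pytest.raises(sf.UndetectableRhythmError):
        sf.detect_r_peaks(flat)


# ---------------------------------------------------------------------------
# heart rate / SDNN


def test_mean_heart_rate_closed_forms():
    beats = sf.BeatSeries(np.cumsum([0.5] + [0.75] * 40))
    assert sf.mean_heart_rate(beats, (0, 40)) == pytest.approx(80.0)
    two = sf.BeatSeries(np.array([1.0, 2.0, 2.5, 3.5, 4.0]))
    # RR = {1.0, 0.5, 1.0, 0.5}: mean 0.75 s -> 80 bpm
    assert sf.mean_heart_rate(two, (0, 5)) == pytest.approx(80.0)


def test_heart_rate_missing_when_all_intervals_masked():
    beats = sf.BeatSeries(np.array([0.5, 2.5, 4.5, 6.5]))  # 30 bpm
    assert np.isnan(sf.mean_heart_rate(beats, (0, 7)))


def test_sdnn_hand_arithmetic():
    const = sf.BeatSeries(np.cumsum([0.5] + [0.8] * 20))
    assert sf.sdnn(const, (0, 20)) == pytest.approx(0.0, abs=1e-9)
    pair = sf.BeatSeries(np.array([0.1, 0.9, 1.9]))  # RR 0.8, 1.0
    assert sf.sdnn(pair, (0, 2)) == pytest.approx(100.0)
    alt = sf.BeatSeries(np.cumsum([0.5] + [1.05, 0.95] * 30))
    assert sf.sdnn(alt, (0, 61)) == pytest.approx(50.0, abs=1e-6)


def test_sdnn_scale_equivariance():
    rng = np.random.default_rng(3)
    dev = rng.normal(0, 0.03, 100)
    for c in (0.5, 2.0):
        a = sf.BeatSeries(np.cumsum(np.concatenate([[0.5], 1.0 + dev])))
        b = sf.BeatSeries(np.cumsum(np.concatenate([[0.5], 1.0 + c * dev])))
        w = (0, 120)
        assert sf.sdnn(b, w) == pytest.approx(c * sf.sdnn(a, w), rel=1e-9)


# ---------------------------------------------------------------------------
# spectral HRV


def _tone_beats(freq, amp_s=0.05, hr=60.0, duration=300.0):
    t, times = 0.5, []
    while t < duration:
        times.append(t)
        t += 60.0 / hr + amp_s * np.sin(2 * np.pi * freq * t)
    return sf.BeatSeries(np.array(times))


@pytest.mark.parametrize("freq,check", [
    (0.10, lambda r: r > 10),    # LF tone dominates
    (0.30, lambda r: r < 0.1),   # HF tone dominates
])
def test_single_tone_ratio(freq, check):
    _, _, ratio = sf.hrv_spectrum(_tone_beats(freq), (0, 300))
    assert check(ratio)


def test_single_tone_band_concentration():
    """>= 90% of the two-band power lands in the band holding the tone."""
    for freq, band in ((0.10, "lf"), (0.30, "hf")):
        lf, hf, _ = sf.hrv_spectrum(_tone_beats(freq), (0, 300))
        share = (lf if band == "lf" else hf) / (lf + hf)
        assert share >= 0.90


def test_constant_rr_has_no_band_power():
    beats = sf.BeatSeries(np.arange(0.5, 300.0, 1.0))
    lf, hf, ratio = sf.hrv_spectrum(beats, (0, 300))
    assert lf == pytest.approx(0.0, abs=1e-12)
    assert hf == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(ratio) or ratio == 0


def test_tone_power_matches_plain_fft_oracle():
    """Band powers agree in order of magnitude with a direct periodogram
    of the same interpolated tachogram (no Welch averaging)."""
    beats = _tone_beats(0.10)
    lf, hf, _ = sf.hrv_spectrum(beats, (0, 300))
    # oracle: plain rFFT periodogram of the 4 Hz linearly resampled series
    t = beats.r_peak_times_s[1:]
    rr = beats.rr_intervals_s
    grid = np.arange(t[0], t[-1], 0.25)
    x = np.interp(grid, t, rr)
    x = x - np.polyval(np.polyfit(grid, x, 1), grid)
    spec = np.abs(np.fft.rfft(x)) ** 2 / (x.size * 4.0)
    freqs = np.fft.rfftfreq(x.size, 0.25)
    lf_oracle = 2 * np.sum(spec[(freqs >= 0.04) & (freqs < 0.15)]) * (
        freqs[1] - freqs[0])
    assert lf == pytest.approx(lf_oracle, rel=0.5)
    assert lf > 100 * hf


# ---------------------------------------------------------------------------
# respiration and RSA


def test_respiration_rate_from_sinusoid():
    t = np.arange(0, 60.0, 1 / FS)
    resp = ChannelSignal("respiration", np.sin(2 * np.pi * 0.25 * t), FS)
    cycles = sf.respiratory_cycles(resp, (0, 60))
    assert cycles.rate_breaths_per_min == pytest.approx(15.0, abs=0.3)
    resp12 = ChannelSignal("respiration", np.sin(2 * np.pi * 0.2 * t), FS)
    c12 = sf.respiratory_cycles(resp12, (0, 60))
    assert c12.rate_breaths_per_min == pytest.approx(12.0, abs=0.3)


def test_dc_respiration_has_no_cycles():
    resp = ChannelSignal("respiration", np.full(int(60 * FS), 2.0), FS)
    assert sf.respiratory_cycles(resp, (0, 60)) is None


def test_rsa_zero_for_constant_rate():
    beats = sf.BeatSeries(np.arange(0.5, 120.0, 1.0))
    bounds = np.arange(0.0, 120.0, 4.0)
    cycles = sf.RespCycleSeries(bounds, 15.0)
    assert sf.rsa_peak_valley(beats, cycles) == pytest.approx(0.0)


def test_rsa_missing_with_single_beat_cycles():
    beats = sf.BeatSeries(np.arange(0.5, 60.0, 3.9))
    cycles = sf.RespCycleSeries(np.arange(0.0, 60.0, 4.0), 15.0)
    assert np.isnan(sf.rsa_peak_valley(beats, cycles))


@pytest.mark.parametrize("amp", [4.0, 6.0])
def test_rsa_amplitude_recovered_within_15pct(amp):
    rng = np.random.default_rng(5)
    beats_t = syn.synth_beat_times({"w": 70.0}, {"w": 300.0}, amp, 15.0,
                                   0.0, rng)
    beats = sf.BeatSeries(beats_t)
    cycles = sf.RespCycleSeries(np.arange(0.0, 300.0, 4.0), 15.0)
    rsa = sf.rsa_peak_valley(beats, cycles)
    assert rsa == pytest.approx(amp, rel=0.15)


# ---------------------------------------------------------------------------
# electrodermal activity


def _eda(scr_rate, amp=0.3, duration=300.0, tonic=4.0, noise=0.005, seed=2):
    rng = np.random.default_rng(seed)
    return syn.synth_eda({"w": tonic}, {"w": scr_rate}, {"w": duration},
                         amp, noise, FS, rng)


def test_edr_rate_round_trip():
    edr = sf.detect_edr(_eda(5.0), (0, 300))
    assert edr.rate_per_min == pytest.approx(5.0, abs=1.0)
    assert edr.scl_tonic_uS == pytest.approx(4.0, abs=0.3)


def test_pure_tonic_drift_yields_zero_events():
    t = np.arange(0, 120.0, 1 / FS)
    drift = ChannelSignal("eda", 4.0 + 0.5 * np.sin(2 * np.pi * 0.01 * t),
                          FS)
    assert sf.detect_edr(drift, (0, 120)).rate_per_min == 0.0


def test_subthreshold_oscillation_not_counted():
    t = np.arange(0, 120.0, 1 / FS)
    weak = ChannelSignal("eda", 4.0 + 0.01 * np.sin(2 * np.pi * 0.2 * t),
                         FS)
    assert sf.detect_edr(weak, (0, 120)).rate_per_min == 0.0


def test_edr_count_invariant_to_added_tonic_drift():
    eda = _eda(4.0, noise=0.0)
    base = sf.detect_edr(eda, (0, 300)).rate_per_min
    t = np.arange(eda.samples.size) / FS
    drifted = ChannelSignal(
        "eda", eda.samples + 0.5 * np.sin(2 * np.pi * 0.01 * t), FS)
    assert sf.detect_edr(drifted, (0, 300)).rate_per_min == base


def test_flat_eda_rate_zero_with_scl():
    flat = ChannelSignal("eda", np.full(int(120 * FS), 3.3), FS)
    edr = sf.detect_edr(flat, (0, 120))
    assert edr.rate_per_min == 0.0
    assert edr.scl_tonic_uS == pytest.approx(3.3)


def test_tonic_level_round_trip():
    edr = sf.detect_edr(_eda(0.0, tonic=4.0, noise=0.0), (0, 300))
    assert edr.scl_tonic_uS == pytest.approx(4.0, abs=0.05)


# ---------------------------------------------------------------------------
# EMG


def test_emg_rms_constant_and_sinusoid():
    const = ChannelSignal("emg", np.full(int(10 * FS), -0.3), FS)
    assert sf.emg_rms(const, (0, 10)) == pytest.approx(0.3)
    t = np.arange(0, 10.0, 1 / FS)
    sine = ChannelSignal("emg", np.sin(2 * np.pi * 50.0 * t), FS)
    assert sf.emg_rms(sine, (0, 10)) == pytest.approx(1 / np.sqrt(2),
                                                      abs=0.01)


def test_emg_rms_gaussian_noise_matches_sigma():
    rng = np.random.default_rng(8)
    noise = ChannelSignal("emg", rng.normal(0, 0.1, int(60 * FS)), FS)
    assert sf.emg_rms(noise, (0, 60)) == pytest.approx(0.1, abs=0.01)


def test_emg_rms_equals_brute_force_blocks():
    rng = np.random.default_rng(9)
    x = rng.normal(0, 0.2, int(10 * FS))
    emg = ChannelSignal("emg", x, FS)
    got = sf.emg_rms(emg, (0, 10))
    blocks = [x[i:i + 100] for i in range(0, x.size - 99, 100)]
    oracle = np.mean([np.sqrt(sum(v * v for v in b) / 100) for b in blocks])
    assert got == pytest.approx(oracle, rel=1e-12)


# ---------------------------------------------------------------------------
# orchestration


def test_extract_features_covers_all_phases(tiny_session):
    recording, _, _, truth = tiny_session
    feats = sf.extract_features(recording)
    assert len(feats) == 7
    assert list(feats["phase"]) == [p.phase for p in sorted(
        recording.phases, key=lambda p: p.start_s)]
    # stepped HR recovered per phase within 1 bpm of the generator target
    for _, row in feats.iterrows():
        assert row["hr_bpm"] == pytest.approx(
            truth[f"true_hr_{row['phase']}"], abs=1.0)


def test_extract_features_without_eda(tiny_session):
    recording, _, _, _ = tiny_session
    no_eda = type(recording)(
        subject_id=recording.subject_id, group=recording.group,
        channels={k: v for k, v in recording.channels.items()
                  if k != "eda"},
        phases=recording.phases,
    )
    feats = sf.extract_features(no_eda)
    assert feats["scl_uS"].isna().all()
    assert feats["edr_per_min"].isna().all()
    assert feats["hr_bpm"].notna().all()
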