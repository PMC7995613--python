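"""Trace idealization: filtering, level estimation, threshold crossing,
resolution imposition."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from chanpopen.dwells import DwellSequence, Trace
from chanpopen.filtering import RISE_FC, cascade_fc, gaussian_lowpass, sigma_from_fc
from chanpopen.gating_sim import SimConfig, render_trace
from chanpopen.idealize import (
    IdealizationSettings,
    detect_events,
    estimate_levels,
    gaussian_filter,
    idealize_trace,
    impose_resolution,
    subconductance_fraction,
)


def brute_force_impose_resolution(records, dead_time):
    """Independent reference: rescan from the start after every merge."""
    items = [list(r) for r in records]
    changed = True
    while changed:
        changed = False
        # merge equal neighbours first
        i = 1
        while i < len(items):
            if items[i][0] == items[i - 1][0] and items[i][1] == items[i - 1][1]:
                items[i - 1][2] += items[i][2]
                del items[i]
            else:
                i += 1
        for i, (s, c, d) in enumerate(items):
            if d < dead_time and len(items) > 1:
                if i == 0:
                    items[1][2] += d
                    del items[0]
                elif i == len(items) - 1:
                    items[-2][2] += d
                    del items[-1]
                else:
                    items[i - 1][2] += d + items[i + 1][2]
                    del items[i : i + 2]
                changed = True
                break
    return [tuple(it) for it in items]


# --- Gaussian filtering ---------------------------------------------------

def test_filter_constant_trace_unchanged():
    trace = Trace(np.full(1000, 2.5, np.float32), fs=10_000.0)
    out = gaussian_filter(trace, 1_000.0)
    assert np.allclose(out.samples, 2.5, atol=1e-6)


def test_filter_step_rise_time():
    fs, fc = 100_000.0, 3_000.0
    x = np.concatenate([np.zeros(2000), np.ones(2000)])
    y = gaussian_lowpass(x, fc, fs)
    t = np.arange(x.size) / fs
    t10 = np.interp(0.1, y[1500:2500], t[1500:2500])
    t90 = np.interp(0.9, y[1500:2500], t[1500:2500])
    assert abs((t90 - t10) - RISE_FC / fc) < 2 / fs


def test_filter_noise_bandwidth(rng):
    """Output noise SD follows sigma/sqrt(2*sigma_t*fs*sqrt(pi))."""
    fs, fc, sd = 100_000.0, 3_000.0, 1.0
    x = rng.normal(0, sd, 200_000)
    y = gaussian_lowpass(x, fc, fs)
    expected = sd / np.sqrt(2.0 * sigma_from_fc(fc) * fs * np.sqrt(np.pi))
    assert abs(y.std() - expected) / expected < 0.10


def test_filter_matches_scipy_reference(rng):
    """Cross-check the kernel against an independent Gaussian filter."""
    fs, fc = 50_000.0, 2_000.0
    x = rng.normal(0, 1, 5_000)
    ours = gaussian_lowpass(x, fc, fs)
    ref = gaussian_filter1d(x, sigma=sigma_from_fc(fc) * fs, mode="reflect", truncate=4.0)
    assert np.allclose(ours, ref, atol=5e-4)


def test_filter_cascade_metadata():
    trace = Trace(np.zeros(100, np.float32), fs=40_000.0, fc=10_000.0)
    out = gaussian_filter(trace, 3_000.0)
    assert out.fc == pytest.approx(cascade_fc(10_000.0, 3_000.0))
    assert out.fc == pytest.approx(1.0 / np.sqrt(1 / 10_000.0**2 + 1 / 3_000.0**2))


def test_filter_above_nyquist_rejected():
    trace = Trace(np.zeros(100, np.float32), fs=10_000.0)
    with pytest.raises(ValueError):
        gaussian_filter(trace, 6_000.0)


# --- level estimation -----------------------------------------------------

def test_estimate_levels_two_level_trace():
    t = Trace(np.array([0.0] * 700 + [5.0] * 300, np.float32), fs=1000.0)
    baseline, amplitude = estimate_levels(t)
    assert baseline == pytest.approx(0.0, abs=0.05)
    assert amplitude == pytest.approx(5.0, abs=0.05)


def test_estimate_levels_translation_equivariance():
    t0 = Trace(np.array([0.0] * 700 + [5.0] * 300, np.float32), fs=1000.0)
    t1 = Trace(t0.samples + 1.0, fs=1000.0)
    b0, a0 = estimate_levels(t0)
    b1, a1 = estimate_levels(t1)
    assert b1 - b0 == pytest.approx(1.0, abs=0.05)
    assert a1 == pytest.approx(a0, abs=0.05)


def test_estimate_levels_recovers_generator_amplitude(taurine_recording):
    _, config, _, trace = taurine_recording
    baseline, amplitude = estimate_levels(trace)
    assert abs(amplitude - config.amplitude) / config.amplitude < 0.05


def test_estimate_levels_unimodal_raises(rng):
    t = Trace(rng.normal(0, 0.5, 50_000).astype(np.float32), fs=1000.0)
    with pytest.raises(ValueError, match="amplitude"):
        estimate_levels(t)


# --- event detection ------------------------------------------------------

def test_detect_all_baseline_trace():
    t = Trace(np.zeros(5000, np.float32), fs=33_333.0)
    dwells = detect_events(t, IdealizationSettings(amplitude=5.0))
    assert np.all(dwells.state_class == "shut")
    assert dwells.total_duration == pytest.approx(t.duration)


def test_detect_rectangular_event_duration():
    """A filtered 10 ms 5 pA event idealizes to one 10 ms open dwell."""
    seq = DwellSequence.from_records(
        [("shut", "zero", 0.02), ("open", "full", 0.01), ("shut", "zero", 0.02)]
    )
    cfg = SimConfig(duration=0.05, noise_sd=0.0, seed=0)
    trace = render_trace(seq, cfg)
    dwells = detect_events(trace, IdealizationSettings(amplitude=5.0))
    opens = dwells.durations[np.asarray(dwells.state_class == "open")]
    assert opens.size == 1
    assert abs(opens[0] - 0.01) < 1.0 / trace.fs


def test_subconductance_event_classified_shut():
    """A 1 pA event never crosses the 2.5 pA half-amplitude threshold."""
    seq = DwellSequence.from_records(
        [("shut", "zero", 0.02), ("open", "sub", 0.01), ("shut", "zero", 0.02)]
    )
    cfg = SimConfig(duration=0.05, noise_sd=0.0, seed=0)
    trace = render_trace(seq, cfg)
    dwells = detect_events(trace, IdealizationSettings(amplitude=5.0))
    assert np.all(dwells.state_class == "shut")
    # ... but the diagnostic sees it as a sub-level dwell
    frac = subconductance_fraction(trace, IdealizationSettings(amplitude=5.0))
    assert frac == pytest.approx(0.01 / 0.05, rel=0.2)


def test_threshold_polarity_symmetry():
    seq = DwellSequence.from_records(
        [("shut", "zero", 0.02), ("open", "full", 0.01), ("shut", "zero", 0.02)]
    )
    cfg = SimConfig(duration=0.05, noise_sd=0.2, seed=13)
    trace = render_trace(seq, cfg)
    inverted = Trace(-trace.samples, fs=trace.fs, fc=trace.fc)
    d1 = detect_events(trace, IdealizationSettings(amplitude=5.0))
    d2 = detect_events(inverted, IdealizationSettings(amplitude=-5.0), amplitude=-5.0)
    assert np.array_equal(d1.state_class, d2.state_class)
    assert np.allclose(d1.durations, d2.durations)


def test_detection_duration_conservation(taurine_recording):
    _, _, _, trace = taurine_recording
    dwells = detect_events(trace, IdealizationSettings(amplitude=5.0))
    assert dwells.total_duration == pytest.approx(trace.duration, abs=1.0 / trace.fs)
    resolved = impose_resolution(dwells, 60e-6)
    assert resolved.total_duration == pytest.approx(
        trace.duration, abs=1.0 / trace.fs
    )


# --- resolution imposition ------------------------------------------------

def test_impose_resolution_identity():
    seq = DwellSequence.from_records(
        [("shut", "zero", 0.005), ("open", "full", 0.005), ("shut", "zero", 0.005)]
    )
    out = impose_resolution(seq, 1e-4)
    assert np.array_equal(out.durations, seq.durations)
    assert np.array_equal(out.state_class, seq.state_class)


def test_impose_resolution_forced_merge():
    seq = DwellSequence.from_records(
        [("open", "full", 0.005), ("shut", "zero", 0.00005), ("open", "full", 0.005)]
    )
    out = impose_resolution(seq, 1e-4)
    assert len(out) == 1
    assert out.state_class[0] == "open"
    assert out.durations[0] == pytest.approx(0.01005, abs=1e-12)


def test_impose_resolution_matches_brute_force(rng):
    """Random alternating sequences match the independent rescanning merger."""
    for _ in range(50):
        n = rng.integers(2, 12)
        records = []
        state = rng.integers(0, 2)
        for i in range(n):
            cls = ("open", "full") if (state + i) % 2 else ("shut", "zero")
            records.append((cls[0], cls[1], float(rng.choice([0.00003, 0.0002, 0.001]))))
        seq = DwellSequence.from_records(records)
        out = impose_resolution(seq, 1e-4)
        ref = brute_force_impose_resolution(records, 1e-4)
        assert [tuple(d[:2]) for d in out] == [r[:2] for r in ref]
        assert np.allclose(out.durations, [r[2] for r in ref], atol=1e-15)
        assert out.total_duration == pytest.approx(seq.total_duration, rel=1e-12)
        if len(out) > 1:
            assert np.all(out.durations >= 1e-4)


# --- end-to-end fidelity --------------------------------------------------

def test_pipeline_recovers_well_resolved_dwells(rng):
    """All dwells ≫ dead time, low noise: counts equal, durations within 2 samples."""
    records = [("shut", "zero", 0.004)]
    for _ in range(30):
        records.append(("open", "full", float(rng.uniform(0.002, 0.01))))
        records.append(("shut", "zero", float(rng.uniform(0.002, 0.01))))
    seq = DwellSequence.from_records(records)
    cfg = SimConfig(duration=seq.total_duration, noise_sd=0.4, seed=21)
    trace = render_trace(seq, cfg)
    recovered = idealize_trace(trace, IdealizationSettings(amplitude=5.0))
    gen_open = seq.durations[np.asarray(seq.state_class == "open")]
    rec_open = recovered.durations[np.asarray(recovered.state_class == "open")]
    assert rec_open.size == gen_open.size
    assert np.all(np.abs(rec_open - gen_open) < 2.0 / trace.fs)
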