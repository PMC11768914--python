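"""FDMA excitation, resonator, equalizer design and matched-filter demodulation."""

import numpy as np
import pytest
from scipy import signal as sps

from magdist.dipole import PoseSample, field_matrix
from magdist.estimator import estimate_distance
from magdist.signal_chain import (
    ChannelMap,
    ExcitationConfig,
    PeakFilterEqualizer,
    PeakFilterParams,
    ResonatorInverseEqualizer,
    ResonatorModel,
    SpectrumEstimate,
    apply_resonator,
    assemble_field_matrices,
    demodulate,
    design_peak_filter,
    estimate_amplitude_response,
    fit_bandpass,
    peak_filter_response,
    sweep_fit_equalizer,
    synthesize_excitation,
)
from magdist.synthetic import render_sensor_voltage

FS = 48000.0


# ---------------------------------------------------------------------------
# Excitation
# ---------------------------------------------------------------------------


def test_single_tone_sample_count_and_peak():
    cfg = ExcitationConfig(tone_frequencies_hz=(7425.0,))
    x = synthesize_excitation(cfg, 1.0)
    assert x.shape == (1, 48000)
    assert np.max(np.abs(x)) == pytest.approx(1.0, abs=1e-6)


def test_six_default_tones_give_six_spectral_lines():
    cfg = ExcitationConfig()
    x = synthesize_excitation(cfg, 1.0).sum(axis=0)
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, 1.0 / FS)
    peaks = freqs[spec > 0.1 * spec.max()]
    np.testing.assert_allclose(sorted(peaks), cfg.tone_frequencies_hz, atol=0.5)


def test_zero_envelope_gives_zero_stream():
    cfg = ExcitationConfig(tone_frequencies_hz=(7425.0,))
    x = synthesize_excitation(cfg, 0.5, envelopes=np.zeros(24000))
    assert not np.any(x)


def test_wideband_envelope_rejected():
    cfg = ExcitationConfig()
    t = np.arange(48000) / FS
    env = 1.0 + np.cos(2 * np.pi * 40.0 * t)  # 40 Hz > half the 50 Hz spacing
    with pytest.raises(ValueError):
        synthesize_excitation(cfg, 1.0, envelopes=np.tile(env, (6, 1)))


def test_excitation_config_validation():
    with pytest.raises(ValueError):
        ExcitationConfig(tone_frequencies_hz=(7425.0, 7425.0))
    with pytest.raises(ValueError):
        ExcitationConfig(tone_frequencies_hz=(7425.0, 7440.0))  # 15 Hz spacing
    with pytest.raises(ValueError):
        ExcitationConfig(filter_length_s=0.0401234)
    with pytest.raises(ValueError):
        synthesize_excitation(ExcitationConfig(), 1.0, noise_std=0.1)  # no rng


def test_frame_rate_is_sample_rate_over_frame_length():
    cfg = ExcitationConfig()
    assert cfg.frame_rate_hz == 93.75
    x = synthesize_excitation(ExcitationConfig(tone_frequencies_hz=(7425.0,)), 1.0)
    fr = demodulate(x, ExcitationConfig(tone_frequencies_hz=(7425.0,)))
    assert fr.frame_rate_hz == 93.75
    dt = np.diff(fr.time_s)
    np.testing.assert_allclose(dt, 512.0 / FS, rtol=1e-12)


# ---------------------------------------------------------------------------
# Resonator
# ---------------------------------------------------------------------------


def test_resonator_peak_and_edges():
    mod = ResonatorModel(f_res_hz=7550.0, bandwidth_hz=30.0, peak_sensitivity=2.0)
    t = np.arange(int(2 * FS)) / FS
    for f, expect, tol in [
        (7550.0, 2.0, 0.001),
        (7535.0, 2.0 / np.sqrt(2), 0.01),
        (7565.0, 2.0 / np.sqrt(2), 0.01),
    ]:
        y = apply_resonator(np.cos(2 * np.pi * f * t), mod, FS)
        amp = np.max(np.abs(y[24000:72000]))
        assert amp == pytest.approx(expect, rel=tol)


def test_resonator_blocks_dc():
    mod = ResonatorModel(f_res_hz=7550.0, bandwidth_hz=30.0)
    y = apply_resonator(np.ones(48000), mod, FS)
    assert np.max(np.abs(y)) < 1e-6


def test_resonator_validation():
    with pytest.raises(ValueError):
        ResonatorModel(f_res_hz=7550.0, bandwidth_hz=0.0)


# ---------------------------------------------------------------------------
# Amplitude-response estimation
# ---------------------------------------------------------------------------


def _bandnoise(rng, duration_s):
    n = int(duration_s * FS)
    v = rng.standard_normal(n)
    b, a = sps.butter(4, [6000 / 24000, 9000 / 24000], btype="band")
    return sps.lfilter(b, a, v)


def test_response_of_identical_streams_is_unity(rng):
    v = _bandnoise(rng, 5.0)
    spec = estimate_amplitude_response(v, v, FS)
    np.testing.assert_allclose(spec.amplitude, 1.0, atol=1e-12)


def test_response_of_scaled_stream_is_the_scale(rng):
    v = _bandnoise(rng, 5.0)
    spec = estimate_amplitude_response(2.0 * v, v, FS)
    np.testing.assert_allclose(spec.amplitude, 2.0, atol=1e-9)


def test_response_recovers_resonator_within_half_db(rng):
    mod = ResonatorModel(f_res_hz=7550.0, bandwidth_hz=30.0, peak_sensitivity=2.0)
    v = _bandnoise(rng, 12.0)
    y = apply_resonator(v, mod, FS)
    spec = estimate_amplitude_response(y, v, FS, band_hz=(6500.0, 8500.0))
    analytic = np.abs(mod.response(spec.frequencies_hz))
    dev_db = np.abs(20 * np.log10(spec.amplitude / analytic))
    assert np.max(dev_db) < 0.5


def test_response_rejects_silent_reference():
    with pytest.raises(ValueError):
        estimate_amplitude_response(np.ones(48000), np.zeros(48000), FS)


# ---------------------------------------------------------------------------
# Bandpass fit and peak-filter design
# ---------------------------------------------------------------------------


def test_fit_bandpass_on_analytic_resonance():
    mod = ResonatorModel(f_res_hz=7550.0, bandwidth_hz=20.0)
    f = np.arange(6000.0, 9000.1, 1.0)
    spec = SpectrumEstimate(frequencies_hz=f, amplitude=np.abs(mod.response(f)))
    fit = fit_bandpass(spec)
    assert abs(fit.f0_hz - 7550.0) <= 1.0  # within one grid step
    assert abs(fit.bw_hz - 20.0) <= 2.0  # within two grid steps


def test_fit_bandpass_flat_spectrum_raises():
    f = np.arange(7000.0, 8000.0, 1.0)
    with pytest.raises(ValueError):
        fit_bandpass(SpectrumEstimate(frequencies_hz=f, amplitude=np.ones(f.size)))


def test_peak_filter_gain_identity_and_inverse():
    p = PeakFilterParams(f0_hz=7550.0, bw_hz=25.0, gain_db=12.0)
    assert 20 * np.log10(abs(peak_filter_response(p, 7550.0, FS))) == pytest.approx(
        12.0, abs=0.1
    )
    # 0 dB gain -> identity
    p0 = PeakFilterParams(f0_hz=7550.0, bw_hz=25.0, gain_db=0.0)
    f = np.linspace(100.0, 23000.0, 500)
    assert np.max(np.abs(20 * np.log10(np.abs(peak_filter_response(p0, f, FS))))) < 1e-9
    # far skirt back to 0 dB
    skirt = peak_filter_response(p, np.array([7550.0 - 500.0, 7550.0 + 500.0]), FS)
    assert np.max(np.abs(20 * np.log10(np.abs(skirt)))) < 0.2
    # cascade with negated-gain filter is flat
    pinv = PeakFilterParams(f0_hz=7550.0, bw_hz=25.0, gain_db=-12.0)
    fgrid = np.linspace(6000.0, 9000.0, 2000)
    casc = np.abs(peak_filter_response(p, fgrid, FS) * peak_filter_response(pinv, fgrid, FS))
    assert np.max(np.abs(20 * np.log10(casc))) < 0.05


def test_peak_filter_bandwidth_is_minus3db_width():
    p = PeakFilterParams(f0_hz=7550.0, bw_hz=22.4, gain_db=18.0)
    f = np.linspace(7400.0, 7700.0, 300001)
    h = np.abs(peak_filter_response(p, f, FS))
    i = np.argmax(h)
    target = h[i] / np.sqrt(2)
    lo = f[:i][np.argmin(np.abs(h[:i] - target))]
    hi = f[i:][np.argmin(np.abs(h[i:] - target))]
    assert hi - lo == pytest.approx(22.4, abs=0.01)


def test_design_peak_filter_coefficients_normalized():
    b, a = design_peak_filter(PeakFilterParams(7550.0, 25.0, 10.0), FS)
    assert a[0] == 1.0
    w, h = sps.freqz(b, a, worN=[2 * np.pi * 7550.0 / FS])
    assert 20 * np.log10(abs(h[0])) == pytest.approx(10.0, abs=0.1)


# ---------------------------------------------------------------------------
# Sweep fit
# ---------------------------------------------------------------------------


def test_sweep_exact_recovery_and_never_worse_than_init():
    """Spectrum generated by an on-grid peak filter is recovered exactly."""
    true = PeakFilterParams(f0_hz=7550.3, bw_hz=22.4, gain_db=18.0)
    f = np.arange(6000.0, 9000.1, 1.0)
    spec = SpectrumEstimate(
        frequencies_hz=f, amplitude=np.abs(peak_filter_response(true, f, FS))
    )
    init = fit_bandpass(spec)
    best, report = sweep_fit_equalizer(spec, init, sample_rate_hz=FS)
    assert best.f0_hz == pytest.approx(true.f0_hz, abs=1e-9)
    assert best.bw_hz == pytest.approx(true.bw_hz, abs=1e-9)
    assert best.gain_db == pytest.approx(true.gain_db, abs=1e-9)
    assert report["mae_db"] < 1e-9
    assert report["mae_db"] <= report["init_mae_db"]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_sweep_noisy_spectrum_f0_within_tolerance(seed):
    """0.2 dB additive spectral noise moves the center estimate < 0.3 Hz."""
    true = PeakFilterParams(f0_hz=7550.3, bw_hz=22.4, gain_db=18.0)
    f = np.arange(6000.0, 9000.1, 1.0)
    rng = np.random.default_rng(100 + seed)
    amp = np.abs(peak_filter_response(true, f, FS)) * 10 ** (
        rng.normal(0.0, 0.2, f.size) / 20.0
    )
    spec = SpectrumEstimate(frequencies_hz=f, amplitude=amp)
    best, report = sweep_fit_equalizer(spec, fit_bandpass(spec), sample_rate_hz=FS)
    assert abs(best.f0_hz - true.f0_hz) <= 0.3
    assert report["mae_db"] <= report["init_mae_db"]


def test_sweep_rejects_init_outside_band():
    f = np.arange(7400.0, 7700.1, 1.0)
    spec = SpectrumEstimate(frequencies_hz=f, amplitude=np.ones(f.size))
    with pytest.raises(ValueError):
        sweep_fit_equalizer(spec, PeakFilterParams(9000.0, 20.0, 10.0))


# ---------------------------------------------------------------------------
# Demodulation
# ---------------------------------------------------------------------------


def test_demodulation_recovers_amplitude_and_sign():
    cfg = ExcitationConfig(tone_frequencies_hz=(7425.0,), amplitudes=0.7)
    x = synthesize_excitation(cfg, 1.0)
    fr = demodulate(x, cfg)
    assert np.max(np.abs(fr.values[5:, 0, 0] - 0.7)) / 0.7 < 1e-3
    # anti-phase drive -> negated amplitude
    cfg_pi = ExcitationConfig(
        tone_frequencies_hz=(7425.0,), amplitudes=0.7, phases_rad=np.pi
    )
    x_pi = synthesize_excitation(
        ExcitationConfig(tone_frequencies_hz=(7425.0,), amplitudes=0.7), 1.0
    )
    fr_pi = demodulate(x_pi, cfg_pi)
    assert np.max(np.abs(fr_pi.values[5:, 0, 0] + 0.7)) / 0.7 < 1e-3


def test_adjacent_channel_leakage_is_negligible():
    """50 Hz offset = two full cycles over the 40 ms window: an exact null."""
    cfg = ExcitationConfig(tone_frequencies_hz=(7425.0, 7475.0))
    x = synthesize_excitation(ExcitationConfig(tone_frequencies_hz=(7475.0,)), 1.0)
    fr = demodulate(x, cfg, tones_hz=[7425.0])
    leakage = np.max(np.abs(fr.values[5:, 0, 0]))
    assert leakage < 0.005  # spec bound 5%; the orthogonal design achieves ~0


def test_demodulate_unknown_tone_rejected():
    cfg = ExcitationConfig(tone_frequencies_hz=(7425.0,))
    x = synthesize_excitation(cfg, 0.5)
    with pytest.raises(ValueError):
        demodulate(x, cfg, tones_hz=[7475.0])


def test_demodulate_short_stream_rejected():
    cfg = ExcitationConfig(tone_frequencies_hz=(7425.0,))
    with pytest.raises(ValueError):
        demodulate(np.zeros(1000), cfg)


def test_equalized_tones_recover_equal_fields(rng):
    """Characterize -> sweep-fit -> equalize: equal fields agree within 2%."""
    mod = ResonatorModel(f_res_hz=7550.0, bandwidth_hz=30.0, peak_sensitivity=2.0)
    n = int(16 * FS)
    v = _bandnoise(rng, 16.0)
    y = apply_resonator(v, mod, FS)
    spec = estimate_amplitude_response(y, v, FS)
    best, _ = sweep_fit_equalizer(spec, fit_bandpass(spec), sample_rate_hz=FS)
    cfg = ExcitationConfig(tone_frequencies_hz=(7525.0, 7575.0))
    x = synthesize_excitation(cfg, 2.0)
    volt = apply_resonator(x.sum(axis=0), mod, FS)
    eq = PeakFilterEqualizer(best, FS, peak_sensitivity=spec.peak_sensitivity)
    fr = demodulate(volt, cfg, equalizers=[eq], projection="magnitude")
    amps = np.abs(fr.values[20:, 0, :]).mean(axis=0)
    assert abs(amps[0] / amps[1] - 1.0) < 0.02


# ---------------------------------------------------------------------------
# Assembly and end-to-end consistency
# ---------------------------------------------------------------------------


def _static_pose_pipeline(duration_s=1.0):
    cfg = ExcitationConfig()
    pose = PoseSample(position=[0.18, 0.12, -0.08])
    theta = field_matrix(pose)
    resonators = [
        ResonatorModel(7480.0 + 40 * i, 25.0 + 5 * i, 1.5 + 0.3 * i) for i in range(3)
    ]
    volt = render_sensor_voltage(
        np.stack([theta, theta]),
        np.array([0.0, duration_s]),
        cfg,
        resonators,
        coil_tone_indices=(0, 1, 2),
        duration_s=duration_s,
    )
    eqs = [ResonatorInverseEqualizer(m) for m in resonators]
    frames = demodulate(volt, cfg, equalizers=eqs)
    cmap = ChannelMap(
        coil_tones={"A0": {"x": 7425.0, "y": 7475.0, "z": 7525.0}},
        sensor_axes={"S0": {"x": 0, "y": 1, "z": 2}},
    )
    return theta, pose, frames, cmap


def test_end_to_end_static_pose_matches_forward_model():
    theta, pose, frames, cmap = _static_pose_pipeline()
    out = assemble_field_matrices({"S0": frames}, cmap)
    th_meas, times = out["A0-S0"]
    th_avg = th_meas[times > 0.5].mean(axis=0)
    assert np.max(np.abs(th_avg - theta) / np.abs(theta)) < 0.01
    assert abs(estimate_distance(th_avg) - pose.r) / pose.r < 0.005


def test_assembly_respects_channel_permutation():
    theta, _, frames, cmap = _static_pose_pipeline()
    permuted = ChannelMap(
        coil_tones=cmap.coil_tones,
        sensor_axes={"S0": {"x": 1, "y": 0, "z": 2}},  # swap x/y channels
    )
    a = assemble_field_matrices({"S0": frames}, cmap)["A0-S0"][0]
    b = assemble_field_matrices({"S0": frames}, permuted)["A0-S0"][0]
    np.testing.assert_array_equal(b[:, 0, :], a[:, 1, :])
    np.testing.assert_array_equal(b[:, 1, :], a[:, 0, :])


def test_assembly_missing_tone_rejected():
    _, _, frames, _ = _static_pose_pipeline()
    bad = ChannelMap(
        coil_tones={"A0": {"x": 7425.0, "y": 7475.0, "z": 7999.0}},
        sensor_axes={"S0": {"x": 0, "y": 1, "z": 2}},
    )
    with pytest.raises(ValueError):
        assemble_field_matrices({"S0": frames}, bad)


def test_channel_map_requires_three_axes():
    with pytest.raises(ValueError):
        ChannelMap(coil_tones={"A0": {"x": 7425.0}}, sensor_axes={})
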