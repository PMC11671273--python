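"""Synthetic-column generator: determinism, physics, forward model."""

import numpy as np
import pytest

from laminargamma.laminar import Domain
from laminargamma.session import (Attention, Condition, CsdTrial,
                                  TrialEpochs, write_session)
from laminargamma.synth import (OscillatorSpec, _realize_trial,
                                _ricker_profile, build_ground_truth,
                                forward_model_lfp, simulate_session,
                                synthesize_ground_truth_csd,
                                synthesize_spiking)


def test_defaults_carry_reported_frequencies(default_gt):
    freqs = {o.domain: o.base_freq_hz for o in default_gt.oscillators}
    assert freqs[Domain.SG] == 67.0
    assert freqs[Domain.G] == 70.7
    assert freqs[Domain.IG] == 65.3
    sg = default_gt.oscillator(Domain.SG)
    assert sg.freq_hz(Attention.ATTEND_IN) == pytest.approx(68.2)
    assert sg.freq_hz(Attention.ATTEND_AWAY) == pytest.approx(66.0)
    assert sg.freq_hz(Attention.ATTEND_NEARBY) == pytest.approx(66.3)


def test_oscillator_frequency_bounds():
    with pytest.raises(ValueError):
        OscillatorSpec(Domain.G, center_depth_um=900.0, spatial_sd_um=100.0,
                       base_freq_hz=200.0)
    with pytest.raises(ValueError):
        build_ground_truth({"oscillators": [
            {"domain": "G", "center_depth_um": 900.0,
             "spatial_sd_um": 100.0, "base_freq_hz": 20.0}]})


def test_build_ground_truth_determinism_and_unknown_keys():
    a = build_ground_truth({"border_um": 700.0}, seed=3)
    b = build_ground_truth({"border_um": 700.0}, seed=3)
    assert a == b
    with pytest.raises(ValueError):
        build_ground_truth({"no_such_knob": 1})


def test_ricker_profile_integrates_to_zero():
    z = np.arange(0.0, 3100.0, 5.0)
    p = _ricker_profile(z, 1400.0, 130.0)
    assert p[np.argmin(np.abs(z - 1400.0))] == pytest.approx(1.0)
    assert abs(np.trapezoid(p, z)) < 1e-6 * np.abs(p).max() * (z[-1] - z[0])


def test_true_csd_depth_integral_near_zero(default_gt):
    """Balanced sinks/sources: instantaneous depth integral ~ 0."""
    rng = np.random.default_rng(0)
    ep = TrialEpochs(fs_raw=default_gt.fs_raw)
    cond = Condition(attention="attend_in")
    r = _realize_trial(default_gt, cond, ep, rng)
    csd = synthesize_ground_truth_csd(default_gt, r, rng,
                                      include_noise=False,
                                      include_evoked=False,
                                      include_baseline=False)
    integral = csd.data.sum(axis=0)
    scale = np.abs(csd.data).sum(axis=0).max()
    assert np.max(np.abs(integral)) < 1e-6 * scale


def test_attention_gain_scales_oscillator_amplitude(default_gt):
    ep = TrialEpochs(fs_raw=default_gt.fs_raw)
    r_in = _realize_trial(default_gt, Condition(attention="attend_in"), ep,
                          np.random.default_rng(1))
    r_aw = _realize_trial(default_gt, Condition(attention="attend_away"), ep,
                          np.random.default_rng(1))
    sg = default_gt.oscillator(Domain.SG)
    ratio = (r_in.amp_envelopes[Domain.SG] / r_aw.amp_envelopes[Domain.SG])
    expected = (sg.attention_power_gain[Attention.ATTEND_IN]
                / sg.attention_power_gain[Attention.ATTEND_AWAY])
    np.testing.assert_allclose(ratio, expected, rtol=1e-9)


def test_forward_model_linearity(default_gt):
    rng = np.random.default_rng(2)
    z = default_gt.grid_um
    data = rng.standard_normal((z.size, 20))
    ep = TrialEpochs(fs_raw=default_gt.fs_raw)
    cond = Condition(attention="attend_in")
    csd = CsdTrial(data=data, fs=default_gt.fs_raw, epochs=ep,
                   condition=cond, positions_um=z)
    zero = CsdTrial(data=np.zeros_like(data), fs=default_gt.fs_raw,
                    epochs=ep, condition=cond, positions_um=z)
    double = CsdTrial(data=2.0 * data, fs=default_gt.fs_raw, epochs=ep,
                      condition=cond, positions_um=z)
    assert np.allclose(forward_model_lfp(zero, default_gt.probe), 0.0)
    np.testing.assert_allclose(forward_model_lfp(double, default_gt.probe),
                               2.0 * forward_model_lfp(csd, default_gt.probe),
                               rtol=1e-12)


def test_point_source_potential_peaks_at_nearest_electrode(default_gt):
    z = default_gt.grid_um
    data = np.zeros((z.size, 1))
    k = np.argmin(np.abs(z - default_gt.probe.depth_of(9)))
    data[k, 0] = 1.0
    ep = TrialEpochs(fs_raw=default_gt.fs_raw)
    csd = CsdTrial(data=data, fs=default_gt.fs_raw, epochs=ep,
                   condition=Condition(attention="attend_in"),
                   positions_um=z)
    pot = forward_model_lfp(csd, default_gt.probe)[:, 0]
    assert pot.argmax() == 9
    assert np.all(np.diff(pot[9:]) < 0) and np.all(np.diff(pot[:10]) > 0)


def test_spiking_rate_and_silent_channel(default_gt):
    from dataclasses import replace

    rng = np.random.default_rng(3)
    ep = TrialEpochs(fs_raw=default_gt.fs_raw)
    r = _realize_trial(default_gt, Condition(attention="attend_in"), ep, rng)
    trace = synthesize_spiking(default_gt, r, channel=4,
                               rng=np.random.default_rng(4))
    assert trace.shape == r.gate.shape
    assert np.any(trace != 0.0)
    silent = replace(default_gt, spike_rate_hz=0.0)
    quiet = synthesize_spiking(silent, r, channel=4,
                               rng=np.random.default_rng(4))
    assert np.all(quiet == 0.0)


def test_spike_waveform_energy_above_400hz(default_gt):
    from laminargamma.synth import _spike_waveform

    w = _spike_waveform(default_gt.fs_raw)
    spec = np.abs(np.fft.rfft(w, n=4096)) ** 2
    f = np.fft.rfftfreq(4096, 1.0 / default_gt.fs_raw)
    assert spec[f >= 400.0].sum() / spec.sum() > 0.9


def test_session_labels_balanced_and_deterministic(default_gt, tmp_path):
    s1 = simulate_session(default_gt, n_trials_per_condition=3)
    assert len(s1) == 9
    for att in Attention:
        assert len(s1.select(attention=att)) == 3
    s2 = simulate_session(default_gt, n_trials_per_condition=3)
    write_session(s1, tmp_path / "a")
    write_session(s2, tmp_path / "b")
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


def test_session_rejects_low_sampling_rate(default_gt):
    with pytest.raises(ValueError):
        simulate_session(default_gt, n_trials_per_condition=1, fs_raw=100.0)
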