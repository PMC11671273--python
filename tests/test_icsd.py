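"""Spline iCSD: disc kernel, forward matrix, inversion, smoothing."""

import numpy as np
import pytest

from laminargamma.icsd import (ICsdParams, build_forward_matrix,
                               disc_potential_kernel, evoked_onset_csd,
                               invert_spline_icsd, smooth_depth_profile)
from laminargamma.session import (Condition, CsdTrial, LfpTrial,
                                  ProbeGeometry, TrialEpochs)


def _lfp(data, probe=None):
    return LfpTrial(data=data, fs=1000.0, epochs=TrialEpochs(fs_raw=1000.0),
                    condition=Condition(attention="attend_in"))


def test_kernel_closed_form_and_limits():
    p = ICsdParams()
    # (1/(2 sigma)) * R at zero offset: 500 um / (2 * 0.4 S/m)
    assert disc_potential_kernel(0.0, p) == pytest.approx(6.25e-4, rel=1e-12)
    assert disc_potential_kernel(1e9, p) == pytest.approx(0.0, abs=1e-9)
    tiny_disc = ICsdParams(disc_radius_um=1e-6)
    assert disc_potential_kernel(300.0, tiny_disc) == pytest.approx(0.0,
                                                                    abs=1e-12)
    # monotone decay with distance
    dz = np.linspace(0, 3000, 50)
    k = disc_potential_kernel(dz, p)
    assert np.all(np.diff(k) < 0)


def test_params_validation():
    with pytest.raises(ValueError):
        ICsdParams(disc_radius_um=-1.0)
    with pytest.raises(ValueError):
        ICsdParams(smooth_window_um=300.0, smooth_sd_um=200.0)


def test_forward_matrix_shape_scaling_and_uniform_csd(probe16):
    params = ICsdParams()
    f = build_forward_matrix(probe16, params).matrix
    assert f.shape == (16, 16)
    # uniform CSD: positive potentials, maximal centrally
    phi = f @ np.ones(16)
    assert np.all(phi > 0)
    assert phi.argmax() in range(4, 12)
    # kernel scales as 1/sigma
    half = build_forward_matrix(
        probe16, ICsdParams(conductivity_S_per_m=0.2)).matrix
    np.testing.assert_allclose(half, 2.0 * f, rtol=1e-12)


def test_forward_matrix_grid_refinement(probe16):
    f1 = build_forward_matrix(probe16, quad_step_um=5.0).matrix
    f2 = build_forward_matrix(probe16, quad_step_um=2.5).matrix
    assert np.max(np.abs(f2 - f1)) / np.max(np.abs(f1)) < 1e-3


def test_inversion_recovers_knot_values(probe16):
    """Central oracle: invert(forward(c)) == c to near machine precision."""
    fwd = build_forward_matrix(probe16)
    rng = np.random.default_rng(0)
    c = rng.standard_normal((16, 100))
    phi = fwd.matrix @ c
    csd = invert_spline_icsd(_lfp(phi), fwd)
    err = (np.linalg.norm(csd.data - c, axis=0)
           / np.linalg.norm(c, axis=0))
    assert np.all(err <= 1e-8)


def test_inversion_zero_and_linearity(probe16):
    fwd = build_forward_matrix(probe16)
    zero = invert_spline_icsd(_lfp(np.zeros((16, 10))), fwd)
    assert np.allclose(zero.data, 0.0)
    rng = np.random.default_rng(1)
    phi = rng.standard_normal((16, 20))
    a = invert_spline_icsd(_lfp(phi), fwd).data
    b = invert_spline_icsd(_lfp(2.5 * phi), fwd).data
    np.testing.assert_allclose(b, 2.5 * a, rtol=1e-10)


def test_inversion_channel_mismatch(probe16):
    fwd = build_forward_matrix(probe16)
    with pytest.raises(ValueError):
        invert_spline_icsd(_lfp(np.zeros((8, 10))), fwd)


def test_smoothing_constant_profile_unchanged():
    csd = CsdTrial(data=np.full((16, 5), 3.0), fs=1000.0,
                   epochs=TrialEpochs(fs_raw=1000.0),
                   condition=Condition(attention="attend_in"),
                   positions_um=np.arange(16) * 100.0)
    out = smooth_depth_profile(csd)
    np.testing.assert_allclose(out.data, 3.0, rtol=1e-12)


def test_smoothing_impulse_weights_match_gaussian():
    data = np.zeros((16, 1))
    data[8, 0] = 1.0
    csd = CsdTrial(data=data, fs=1000.0, epochs=TrialEpochs(fs_raw=1000.0),
                   condition=Condition(attention="attend_in"),
                   positions_um=np.arange(16) * 100.0)
    out = smooth_depth_profile(csd).data[:, 0]
    offs = (np.arange(16) - 8) * 100.0
    expect = np.exp(-0.5 * (offs / 200.0) ** 2)
    expect[np.abs(offs) > 500.0] = 0.0
    # rows of the smoothing matrix are unit-sum; the impulse response is the
    # column, each entry normalized by its own row sum
    col = np.array([expect[i] / np.sum(
        np.where(np.abs((np.arange(16) - i) * 100.0) <= 500.0,
                 np.exp(-0.5 * (((np.arange(16) - i) * 100.0) / 200.0) ** 2),
                 0.0)) for i in range(16)])
    np.testing.assert_allclose(out, col, rtol=1e-12)


def test_smoothing_reduces_total_variation():
    rng = np.random.default_rng(3)
    csd = CsdTrial(data=rng.standard_normal((16, 30)), fs=1000.0,
                   epochs=TrialEpochs(fs_raw=1000.0),
                   condition=Condition(attention="attend_in"),
                   positions_um=np.arange(16) * 100.0)
    tv = np.abs(np.diff(csd.data, axis=0)).sum()
    tv_s = np.abs(np.diff(smooth_depth_profile(csd).data, axis=0)).sum()
    assert tv_s < tv


def test_fine_grid_forward_inverse_round_trip(default_gt):
    """Smooth fine-grid CSD recovered at the knots within 2 % relative RMS."""
    from laminargamma.synth import _ricker_profile, forward_model_lfp

    probe = default_gt.probe
    z = default_gt.grid_um
    profile = np.zeros(z.size)
    truth = np.zeros(probe.n_channels)
    for osc in default_gt.oscillators:
        profile += osc.base_amplitude * _ricker_profile(
            z, osc.center_depth_um, osc.spatial_sd_um)
        truth += osc.base_amplitude * _ricker_profile(
            probe.depths_um, osc.center_depth_um, osc.spatial_sd_um)
    true_csd = CsdTrial(data=profile[:, None], fs=default_gt.fs_raw,
                        epochs=TrialEpochs(fs_raw=default_gt.fs_raw),
                        condition=Condition(attention="attend_in"),
                        positions_um=z)
    phi = forward_model_lfp(true_csd, probe)
    fwd = build_forward_matrix(probe)
    rec = np.linalg.solve(fwd.matrix, phi[:, 0])
    err = np.sqrt(np.mean((rec - truth) ** 2) / np.mean(truth ** 2))
    assert err <= 0.02


def test_evoked_onset_requires_rf_trials(probe16):
    lfp = _lfp(np.zeros((16, 3000)))
    no_rf = LfpTrial(data=np.zeros((16, 3000)), fs=1000.0,
                     epochs=TrialEpochs(fs_raw=1000.0),
                     condition=Condition(attention="attend_in",
                                         rf_stim_present=False))
    with pytest.raises(ValueError):
        evoked_onset_csd([no_rf], probe16)
    out = evoked_onset_csd([lfp, no_rf], probe16)
    assert out.data.shape == (16, 250)


def test_evoked_average_of_identical_trials(probe16):
    rng = np.random.default_rng(4)
    data = rng.standard_normal((16, 3000)) * 1e-6
    one = evoked_onset_csd([_lfp(data)], probe16)
    three = evoked_onset_csd([_lfp(data)] * 3, probe16)
    np.testing.assert_allclose(three.data, one.data, rtol=1e-12)
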