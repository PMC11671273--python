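"""Layer-border detection, correlation refinement, domain assignment."""

import numpy as np
import pytest

from laminargamma.laminar import (Domain, assign_domains,
                                  baseline_csd_correlation_matrix,
                                  detect_polarity_inversion,
                                  refine_border_from_correlation)
from laminargamma.session import (Condition, CsdTrial, ProbeGeometry,
                                  TrialEpochs)


def _csd_map(profile, n_t=250):
    data = np.tile(np.asarray(profile, dtype=float)[:, None], (1, n_t))
    return CsdTrial(data=data, fs=1000.0, epochs=TrialEpochs(fs_raw=1000.0),
                    condition=Condition(attention="attend_in"),
                    positions_um=np.arange(len(profile)) * 100.0)


def test_polarity_inversion_constructed_profile():
    # source channels 0-1, sink channels 2-3: border between 100 and 200 um
    profile = [1.0, 1.0, -1.0, -1.0, -0.2, 0.1]
    assert detect_polarity_inversion(_csd_map(profile)) == 150.0


def test_polarity_inversion_requires_sign_change():
    with pytest.raises(ValueError):
        detect_polarity_inversion(_csd_map([1.0] * 8))
    with pytest.raises(ValueError):
        detect_polarity_inversion(_csd_map([1.0, -1.0, 1.0]))  # <6 channels


def test_assign_domains_border_arithmetic():
    probe = ProbeGeometry(16, 100.0)
    asg = assign_domains(750.0, probe)
    assert asg.channels_of(Domain.SG) == list(range(8))
    assert asg.channels_of(Domain.G) == list(range(8, 13))
    assert asg.channels_of(Domain.IG) == list(range(13, 16))
    counts = sum(len(asg.channels_of(d)) for d in Domain)
    assert counts == probe.n_channels
    # channel exactly at the border depth is granular
    asg2 = assign_domains(800.0, probe)
    assert asg2.domain_of(8) == Domain.G


def test_assign_domains_degenerate_border_above_probe():
    probe = ProbeGeometry(16, 100.0)
    asg = assign_domains(-50.0, probe)
    assert asg.channels_of(Domain.SG) == []
    assert asg.domain_of(0) == Domain.G


def test_refinement_finds_block_edge():
    probe = ProbeGeometry(16, 100.0)
    corr = np.full((16, 16), 0.05)
    corr[:7, :7] = 0.9
    corr[7:, 7:] = 0.9
    np.fill_diagonal(corr, 1.0)
    # block edge between channels 6 and 7 = 650 um
    for initial in (450.0, 650.0, 850.0):
        assert refine_border_from_correlation(corr, initial, probe) == 650.0


def test_refinement_uniform_matrix_falls_back():
    probe = ProbeGeometry(16, 100.0)
    corr = np.full((16, 16), 0.5)
    np.fill_diagonal(corr, 1.0)
    assert refine_border_from_correlation(corr, 640.0, probe) == 640.0


def test_correlation_matrix_identical_and_independent_channels():
    rng = np.random.default_rng(0)
    epochs = TrialEpochs(fs_raw=1000.0)
    trials = []
    for _ in range(20):
        shared = rng.standard_normal(5000)
        indep = rng.standard_normal((4, 5000))
        data = np.vstack([shared, shared, indep])
        trials.append(CsdTrial(data=data, fs=1000.0, epochs=epochs,
                               condition=Condition(attention="attend_in"),
                               positions_um=np.arange(6) * 100.0))
    corr = baseline_csd_correlation_matrix(trials)
    assert corr[0, 1] == pytest.approx(1.0, abs=1e-6)
    assert np.all(np.diag(corr) == 1.0)
    indep_block = corr[2:, 2:][~np.eye(4, dtype=bool)]
    assert np.median(np.abs(indep_block)) < 0.25  # low-pass shrinks dof


def test_correlation_matrix_needs_two_trials():
    epochs = TrialEpochs(fs_raw=1000.0)
    trial = CsdTrial(data=np.zeros((4, 5000)), fs=1000.0, epochs=epochs,
                     condition=Condition(attention="attend_in"))
    with pytest.raises(ValueError):
        baseline_csd_correlation_matrix([trial])


def test_border_recovery_on_synthetic_sessions(default_gt):
    """End-to-end: polarity + refinement land within one pitch of truth."""
    from laminargamma.icsd import (build_forward_matrix, evoked_onset_csd,
                                   invert_spline_icsd)
    from laminargamma.preprocess import extract_lfp
    from laminargamma.synth import simulate_session

    session = simulate_session(default_gt,
                               n_trials_per_condition={"attend_in": 6})
    fwd = build_forward_matrix(session.probe)
    lfps = [extract_lfp(t) for t in session.trials]
    evoked = evoked_onset_csd(lfps, session.probe, fwd=fwd)
    initial = detect_polarity_inversion(evoked)
    assert abs(initial - default_gt.border_um) <= 100.0
    csds = [invert_spline_icsd(l, fwd) for l in lfps]
    corr = baseline_csd_correlation_matrix(csds)
    refined = refine_border_from_correlation(corr, initial, session.probe)
    assert abs(refined - default_gt.border_um) <= 100.0
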