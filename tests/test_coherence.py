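"""Phase-locking value, bias correction, profiles and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laminargamma.coherence import (PairKind, attention_phc_contrast,
                                    average_profiles_across_sessions,
                                    expected_plv, normalized_domain_preference,
                                    phase_coherence_tf,
                                    spectrolaminar_phc_profile)


def test_identical_phases_and_fixed_lag_give_unity():
    rng = np.random.default_rng(0)
    phases = rng.uniform(-np.pi, np.pi, (20, 100))
    np.testing.assert_allclose(phase_coherence_tf(phases, phases), 1.0)
    np.testing.assert_allclose(
        phase_coherence_tf(phases, phases - np.pi / 3), 1.0)


def test_plv_bounds_and_min_trials():
    rng = np.random.default_rng(1)
    a = rng.uniform(-np.pi, np.pi, (10, 50))
    b = rng.uniform(-np.pi, np.pi, (10, 50))
    plv = phase_coherence_tf(a, b)
    assert np.all((plv >= 0.0) & (plv <= 1.0))
    with pytest.raises(ValueError):
        phase_coherence_tf(a[:1], b[:1])
    with pytest.raises(ValueError):
        phase_coherence_tf(a, b[:, :10])


@settings(deadline=None, max_examples=25)
@given(st.floats(min_value=-np.pi, max_value=np.pi))
def test_plv_invariant_to_common_phase_offset(offset):
    rng = np.random.default_rng(2)
    a = rng.uniform(-np.pi, np.pi, (8, 30))
    b = rng.uniform(-np.pi, np.pi, (8, 30))
    np.testing.assert_allclose(phase_coherence_tf(a + offset, b),
                               phase_coherence_tf(a, b), atol=1e-12)


def test_expected_plv_closed_form():
    assert expected_plv(1) == pytest.approx(np.sqrt(np.pi) / 2.0)
    assert expected_plv(100) == pytest.approx(0.0886, abs=2e-4)
    assert expected_plv(10**8) < 1e-3
    with pytest.raises(ValueError):
        expected_plv(0)


@pytest.mark.parametrize("n", [10, 50, 100])
def test_expected_plv_matches_monte_carlo(n):
    """EV(N) = sqrt(pi)/(2 sqrt(N)): the mean resultant of uniform phasors."""
    rng = np.random.default_rng(42)
    phases = rng.uniform(0, 2 * np.pi, (20000, n))
    mean_plv = np.abs(np.exp(1j * phases).mean(axis=1)).mean()
    assert mean_plv == pytest.approx(expected_plv(n), rel=0.02)


def test_corrected_phc_of_independent_signals_near_zero():
    rng = np.random.default_rng(3)
    n, reps = 100, 200
    vals = []
    for _ in range(reps):
        a = rng.uniform(-np.pi, np.pi, (n, 1))
        b = rng.uniform(-np.pi, np.pi, (n, 1))
        vals.append(phase_coherence_tf(a, b)[0] - expected_plv(n))
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(reps)
    assert abs(vals.mean()) <= 3 * se


def _phasors(rng, n_trials, n_freq, n_t):
    return np.exp(1j * rng.uniform(-np.pi, np.pi, (n_trials, n_freq, n_t)))


def test_profile_csd_csd_excludes_reference_and_neighbors():
    rng = np.random.default_rng(4)
    ref = _phasors(rng, 10, 3, 40)
    targets = np.stack([_phasors(rng, 10, 3, 40) for _ in range(8)])
    prof = spectrolaminar_phc_profile(ref, targets, [40.0, 50.0, 60.0],
                                      PairKind.CSD_CSD, reference_channel=4)
    assert np.all(np.isnan(prof.values[3:6]))
    assert np.all(np.isfinite(prof.values[[0, 1, 2, 6, 7]]))
    assert prof.n_trials == 10


def test_profile_locked_target_beats_independent():
    rng = np.random.default_rng(5)
    ref = _phasors(rng, 30, 2, 50)
    locked = ref * np.exp(1j * 0.4)
    indep = _phasors(rng, 30, 2, 50)
    targets = np.stack([locked, indep])
    prof = spectrolaminar_phc_profile(ref, targets, [40.0, 60.0],
                                      PairKind.CSD_ESA, reference_channel=0)
    band = prof.gamma_band_mean((35.0, 65.0))
    assert band[0] == pytest.approx(1.0 - expected_plv(30), abs=1e-9)
    assert band[0] > band[1]
    assert abs(band[1]) < 0.2


def test_normalized_preference_ratios():
    x = np.array([0.2, 0.4])
    out = normalized_domain_preference(x, x, x)
    np.testing.assert_allclose(out, 1.0 / 3.0)
    a, b, c = np.array([0.6]), np.array([0.3]), np.array([0.1])
    out = normalized_domain_preference(a, b, c)
    np.testing.assert_allclose(out[:, 0], [0.6, 0.3, 0.1])
    scaled = normalized_domain_preference(5 * a, 5 * b, 5 * c)
    np.testing.assert_allclose(scaled, out)
    bad = normalized_domain_preference(np.array([0.0]), np.array([0.0]),
                                       np.array([0.0]))
    assert np.all(np.isnan(bad))


def test_attention_contrast_partner_selection():
    phc_in = np.array([0.1, 0.5, 0.5, 0.2])
    phc_nb = np.array([0.0, 0.3, 0.4, 0.1])
    p_in, p_nb, partner = attention_phc_contrast(phc_in, phc_nb, [1, 2, 3])
    assert partner == 1  # tie between 1 and 2 goes superficial
    assert (p_in, p_nb) == (0.5, 0.3)
    with pytest.raises(ValueError):
        attention_phc_contrast(phc_in, phc_nb, [])


def test_average_profiles_median_and_coverage():
    depths = np.arange(-300.0, 301.0, 100.0)
    base = np.linspace(0.1, 0.7, depths.size)
    profiles = [(depths, base.copy()) for _ in range(5)]
    profiles[0] = (depths, base + 10.0)  # outlier session
    med = average_profiles_across_sessions(profiles)
    np.testing.assert_allclose(med.to_numpy(), base)
    # a depth present in only 3 of 6 sessions is omitted (3 < ceil(12/3))
    short = [(depths[:-1], base[:-1]) for _ in range(3)]
    full = [(depths, base) for _ in range(3)]
    med6 = average_profiles_across_sessions(short + full)
    assert depths[-1] not in med6.index
    assert depths[0] in med6.index
    with pytest.raises(ValueError):
        average_profiles_across_sessions([(depths, base)])
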