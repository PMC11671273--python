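"""Bias-corrected phase coherence (phase-locking value) across the column.

Phase coherence between two signals at time t and frequency f is the
phase-locking value

    PhC(t, f) = | (1/N) sum_k exp(i (phi_a,k - phi_b,k)) |

over N trials, with phases taken from the Morlet wavelet transforms.  The
PLV of N uniformly random phase relations has expectation

    EV(N) = sqrt(pi) / (2 sqrt(N)),

the expected resultant length of N uniform unit phasors; subtracting it
corrects the trial-count bias and makes sessions with different N
comparable.  Negative corrected values are retained.

Spectrolaminar profiles pair the CSD of a hotspot electrode with ESA (or
CSD) signals at every eligible electrode; CSD-CSD profiles exclude the
reference electrode and its two neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "PairKind",
    "PhcProfile",
    "phase_coherence_tf",
    "expected_plv",
    "spectrolaminar_phc_profile",
    "normalized_domain_preference",
    "attention_phc_contrast",
    "average_profiles_across_sessions",
]


class PairKind(str, Enum):
    CSD_ESA = "csd_esa"
    CSD_CSD = "csd_csd"


@dataclass
class PhcProfile:
    """Bias-corrected PhC values per channel x frequency.

    ``values`` is channels x frequencies; excluded channels are NaN.
    """

    values: np.ndarray
    f0_hz: np.ndarray
    n_trials: int
    kind: PairKind
    reference_channel: int
    bias_corrected: bool = True

    def gamma_band_mean(self, band: tuple[float, float]) -> np.ndarray:
        """Per-channel mean corrected PhC over ``band`` (inclusive)."""
        sel = (self.f0_hz >= band[0]) & (self.f0_hz <= band[1])
        if not sel.any():
            raise ValueError(f"no frequencies inside {band}")
        return self.values[:, sel].mean(axis=1)


def phase_coherence_tf(phases_a: np.ndarray,
                       phases_b: np.ndarray) -> np.ndarray:
    """PLV over trials of the phase difference, per remaining axis.

    ``phases_a``/``phases_b`` are trials x ... arrays of phases in
    radians (or unit phasors as complex values).  Returns the resultant
    length in [0, 1] with the trial axis reduced.
    """
    a = np.asarray(phases_a)
    b = np.asarray(phases_b)
    if a.shape != b.shape:
        raise ValueError("phase arrays must have equal shapes")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    pa = a if np.iscomplexobj(a) else np.exp(1j * a)
    pb = b if np.iscomplexobj(b) else np.exp(1j * b)
    return np.abs(np.mean(pa * np.conj(pb), axis=0))


def expected_plv(n_trials: int) -> float:
    """Expected PLV of ``n_trials`` uniformly random phase relations."""
    if n_trials < 1:
        raise ValueError("need at least 1 trial")
    return float(np.sqrt(np.pi) / (2.0 * np.sqrt(n_trials)))


def spectrolaminar_phc_profile(ref_phasors: np.ndarray,
                               target_phasors: np.ndarray,
                               f0_hz: np.ndarray,
                               kind: PairKind | str,
                               reference_channel: int,
                               include_channels: list[int] | None = None,
                               ) -> PhcProfile:
    """Bias-corrected PhC of one hotspot's CSD against signals across depth.

    Parameters
    ----------
    ref_phasors : complex array, trials x frequencies x time
        Unit phasors of the reference (hotspot CSD) phases.
    target_phasors : complex array, channels x trials x frequencies x time
        Unit phasors of the target signals (ESA or CSD) per channel.
    kind : PairKind
        ``csd_esa`` keeps ``include_channels`` (the ESA two-thirds
        selection); ``csd_csd`` additionally drops the reference channel
        and its two immediate neighbors.
    """
    kind = PairKind(kind)
    n_channels, n_trials = target_phasors.shape[0], target_phasors.shape[1]
    if ref_phasors.shape[0] != n_trials:
        raise ValueError("reference/target trial counts differ")
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    eligible = set(include_channels if include_channels is not None
                   else range(n_channels))
    if kind == PairKind.CSD_CSD:
        eligible -= {reference_channel - 1, reference_channel,
                     reference_channel + 1}
    if not eligible:
        raise ValueError("no eligible target channels")
    ev = expected_plv(n_trials)
    values = np.full((n_channels, ref_phasors.shape[1]), np.nan)
    for ch in sorted(eligible):
        plv_tf = phase_coherence_tf(ref_phasors, target_phasors[ch])
        values[ch] = plv_tf.mean(axis=-1) - ev
    return PhcProfile(values=values, f0_hz=np.asarray(f0_hz, dtype=float),
                      n_trials=n_trials, kind=kind,
                      reference_channel=reference_channel)


def normalized_domain_preference(profile_sg: np.ndarray,
                                 profile_g: np.ndarray,
                                 profile_ig: np.ndarray) -> np.ndarray:
    """Per-depth ratios of three gamma-PhC profiles to their sum.

    Returns a 3 x depth array summing to 1 where defined; depths whose
    summed PhC is not positive (or incomplete) are NaN.
    """
    stacked = np.stack([np.asarray(profile_sg, dtype=float),
                        np.asarray(profile_g, dtype=float),
                        np.asarray(profile_ig, dtype=float)])
    total = stacked.sum(axis=0)
    out = np.full_like(stacked, np.nan)
    ok = np.isfinite(total) & (total > 0)
    out[:, ok] = stacked[:, ok] / total[ok]
    return out


def attention_phc_contrast(gamma_phc_in: np.ndarray,
                           gamma_phc_nearby: np.ndarray,
                           partner_channels: list[int],
                           ) -> tuple[float, float, int]:
    """Gamma-PhC at the best cross-domain partner in both conditions.

    The partner is the channel (restricted to ``partner_channels``, the
    other domain) with the highest attend-in gamma-PhC with the hotspot;
    ties go to the more superficial channel.  Returns
    ``(phc_attend_in, phc_attend_nearby, partner_channel)``.
    """
    if not partner_channels:
        raise ValueError("no partner channels in the other domain")
    vals = [(float(gamma_phc_in[c]), c) for c in partner_channels
            if np.isfinite(gamma_phc_in[c])]
    if not vals:
        raise ValueError("no finite attend-in PhC among partner channels")
    best = max(vals, key=lambda v: (v[0], -v[1]))[1]
    return float(gamma_phc_in[best]), float(gamma_phc_nearby[best]), best


def average_profiles_across_sessions(profiles: list[tuple[np.ndarray, np.ndarray]],
                                     ) -> pd.Series:
    """Depth-aligned median profile across sessions.

    ``profiles`` holds ``(relative_depths_um, values)`` per session, with
    depths relative to the layer-III/IV border.  Depths covered by fewer
    than two-thirds of the sessions (ceiling) are omitted.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 sessions")
    frames = []
    for i, (depths, values) in enumerate(profiles):
        frames.append(pd.Series(np.asarray(values, dtype=float),
                                index=np.asarray(depths, dtype=float),
                                name=i))
    df = pd.concat(frames, axis=1)
    min_cover = int(np.ceil(2 * len(profiles) / 3))
    coverage = df.notna().sum(axis=1)
    return df[coverage >= min_cover].median(axis=1).sort_index()
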