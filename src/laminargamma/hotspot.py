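"""Gamma-power depth profiles and per-domain hotspot electrode selection.

Within each laminar domain (SG, G, IG) the hotspot is the electrode with a
discrete gamma-power peak flanked on both sides by same-domain electrodes
with lower power.  When no such local peak exists, a peak hidden in the
flank of a larger neighboring peak is detected from the power gradient: a
local minimum of the gradient on a rising flank selects the first
electrode of the gradient pair, a local maximum on a falling flank the
second.  If both searches fail the domain has no hotspot.

Inclusion rules: hotspot electrodes must show at least 2.5x the baseline
gamma power during MCs 2/3; ESA targets for phase-coherence profiles are
the two-thirds of electrodes with the strongest attend-in ESA gamma power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .laminar import Domain, LaminarAssignment
from .session import CsdTrial, window_slice
from .spectral import WaveletBank, psd_spectrum, wavelet_transform

__all__ = [
    "DetectionMethod",
    "DomainHotspot",
    "HotspotSet",
    "gamma_power_depth_profile",
    "find_domain_hotspot",
    "check_hotspot_inclusion",
    "select_esa_channels",
]

INCLUSION_RATIO = 2.5


class DetectionMethod(str, Enum):
    LOCAL_PEAK = "local_peak"
    GRADIENT_RISING = "gradient_rising"
    GRADIENT_FALLING = "gradient_falling"
    NONE = "none"


@dataclass(frozen=True)
class DomainHotspot:
    channel: int | None
    method: DetectionMethod
    gamma_power: float | None = None
    passes_inclusion: bool | None = None


@dataclass(frozen=True)
class HotspotSet:
    """One optional hotspot electrode per laminar domain."""

    hotspots: dict[Domain, DomainHotspot]

    def __getitem__(self, domain: Domain | str) -> DomainHotspot:
        return self.hotspots[Domain(domain)]

    def channel(self, domain: Domain | str) -> int | None:
        return self[domain].channel


def gamma_power_depth_profile(csd_trials: list[CsdTrial],
                              bank: WaveletBank,
                              band: tuple[float, float],
                              window: str | tuple[float, float] = "mc23",
                              ) -> np.ndarray:
    """Per-channel mean 1/f-corrected gamma power, averaged across trials.

    For each trial, the CSD of every channel is wavelet transformed at the
    bank frequencies inside ``band``; the corrected PSD is averaged over
    the window and the band, then across trials.
    """
    if not csd_trials:
        raise ValueError("no trials given")
    sub = bank.restrict(band)
    acc = None
    for trial in csd_trials:
        sl = window_slice(trial.epochs, trial.fs, window)
        tfr = wavelet_transform(trial.data, sub)
        # window relative to full trial: transform full trace, average inside
        psd = psd_spectrum(tfr, window=sl, one_over_f_correct=True)
        prof = psd.mean(axis=0)
        acc = prof if acc is None else acc + prof
    return acc / len(csd_trials)


def _local_peaks(p: np.ndarray) -> list[int]:
    return [i for i in range(1, p.size - 1)
            if p[i] > p[i - 1] and p[i] > p[i + 1]]


def find_domain_hotspot(profile: np.ndarray,
                        domain_channels: list[int],
                        ) -> tuple[int | None, DetectionMethod]:
    """Select the hotspot electrode among ``domain_channels``.

    ``profile`` is the full-probe gamma-power profile; ``domain_channels``
    are the channel indices of one domain, ordered superficial to deep.
    Returns ``(channel, method)`` with ``channel`` a full-probe index, or
    ``(None, DetectionMethod.NONE)``.
    """
    if len(domain_channels) < 3:
        return None, DetectionMethod.NONE
    p = np.asarray([profile[c] for c in domain_channels], dtype=float)

    peaks = _local_peaks(p)
    if peaks:
        # ties: larger power first, then more superficial
        best = min(peaks, key=lambda i: (-p[i], i))
        return domain_channels[best], DetectionMethod.LOCAL_PEAK

    g = np.diff(p)
    candidates: list[tuple[float, int, DetectionMethod]] = []
    for j in range(1, g.size - 1):
        if g[j] < g[j - 1] and g[j] < g[j + 1] and g[j - 1] > 0 and g[j + 1] > 0:
            idx = j  # first electrode of the gradient-extremum pair
            candidates.append((p[idx], idx, DetectionMethod.GRADIENT_RISING))
        if g[j] > g[j - 1] and g[j] > g[j + 1] and g[j - 1] < 0 and g[j + 1] < 0:
            idx = j + 1  # second electrode of the pair
            candidates.append((p[idx], idx, DetectionMethod.GRADIENT_FALLING))
    if candidates:
        power, idx, method = max(candidates, key=lambda c: (c[0], -c[1]))
        return domain_channels[idx], method
    return None, DetectionMethod.NONE


def check_hotspot_inclusion(power_mc23: float, power_baseline: float,
                            ratio: float = INCLUSION_RATIO) -> bool:
    """True iff stimulus-period gamma power is >= ``ratio`` x baseline."""
    if power_baseline <= 0:
        raise ValueError("baseline power must be positive")
    if power_mc23 < 0:
        raise ValueError("powers must be nonnegative")
    return bool(power_mc23 >= ratio * power_baseline)


def select_esa_channels(esa_gamma_power: np.ndarray) -> list[int]:
    """The ceil(2N/3) channels with the strongest ESA gamma power.

    Ties are broken toward the more superficial channel.  Returns sorted
    channel indices.
    """
    p = np.asarray(esa_gamma_power, dtype=float)
    if p.size < 3:
        raise ValueError("need at least 3 channels")
    k = math.ceil(2 * p.size / 3)
    order = sorted(range(p.size), key=lambda i: (-p[i], i))
    return sorted(order[:k])


def detect_hotspots(profile: np.ndarray, assignment: LaminarAssignment,
                    baseline_profile: np.ndarray | None = None) -> HotspotSet:
    """Run :func:`find_domain_hotspot` for all three domains.

    When ``baseline_profile`` is given, the 2.5x inclusion flag is
    recorded for each detected hotspot.
    """
    out: dict[Domain, DomainHotspot] = {}
    for domain in Domain:
        chans = assignment.channels_of(domain)
        ch, method = find_domain_hotspot(profile, chans)
        passes = None
        power = None
        if ch is not None:
            power = float(profile[ch])
            if baseline_profile is not None:
                passes = check_hotspot_inclusion(profile[ch],
                                                 float(baseline_profile[ch]))
        out[domain] = DomainHotspot(channel=ch, method=method,
                                    gamma_power=power,
                                    passes_inclusion=passes)
    return HotspotSet(hotspots=out)
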