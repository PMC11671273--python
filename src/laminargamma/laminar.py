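"""Layer-III/IV border detection and laminar domain assignment.

Two complementary procedures locate the border between layer III and
layer IV along the probe: (1) the polarity inversion of the average
stimulus-onset CSD, from the most superficial source to the initial sink
below it, and (2) the block structure of low-frequency (< 15 Hz) baseline
CSD correlations, which typically drops sharply at the border and is used
to refine the first estimate.  Channels above the border are supragranular
(SG); channels within 0.5 mm below it are granular (G); deeper channels
are infragranular (IG).

Sign convention: sinks are negative, sources positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .preprocess import BASELINE_LOWPASS, zero_phase_filter
from .session import CsdTrial, ProbeGeometry, window_slice

__all__ = [
    "Domain",
    "LaminarAssignment",
    "detect_polarity_inversion",
    "baseline_csd_correlation_matrix",
    "refine_border_from_correlation",
    "assign_domains",
    "GRANULAR_THICKNESS_UM",
]

GRANULAR_THICKNESS_UM = 500.0


class Domain(str, Enum):
    SG = "SG"
    G = "G"
    IG = "IG"


@dataclass(frozen=True)
class LaminarAssignment:
    """Layer-III/IV border depth and per-channel domain labels."""

    border_l3l4_um: float
    domains: tuple[Domain, ...]
    probe: ProbeGeometry
    method: str = "polarity"

    def domain_of(self, channel: int) -> Domain:
        return self.domains[channel]

    def channels_of(self, domain: Domain | str) -> list[int]:
        domain = Domain(domain)
        return [i for i, d in enumerate(self.domains) if d == domain]


def detect_polarity_inversion(evoked: CsdTrial,
                              early_window_ms: float = 100.0) -> float:
    """Border depth from the source-over-sink inversion of the onset CSD.

    Averages the evoked CSD map over its first ``early_window_ms`` ms and
    scans from the surface for the first channel whose time-mean is a
    source (positive) immediately followed by a sink (negative); the
    border is the midpoint between that channel pair.
    """
    if evoked.n_channels < 6:
        raise ValueError("evoked CSD map must cover at least 6 electrodes")
    n_early = int(round(early_window_ms * evoked.fs / 1000.0))
    profile = evoked.data[:, :max(n_early, 1)].mean(axis=1)
    pos = (evoked.positions_um if evoked.positions_um is not None
           else np.arange(evoked.n_channels) * 100.0)
    for i in range(profile.size - 1):
        if profile[i] > 0 and profile[i + 1] < 0:
            return float(0.5 * (pos[i] + pos[i + 1]))
    raise ValueError("no source-to-sink polarity inversion found")


def baseline_csd_correlation_matrix(csd_trials: list[CsdTrial],
                                    margin_ms: float = 100.0) -> np.ndarray:
    """Median across trials of baseline low-frequency CSD correlations.

    Per trial the CSD is low-pass filtered (pass 15 Hz, stop 20 Hz, 35 dB,
    zero phase) and Pearson correlations between every channel pair are
    computed from ``margin_ms`` after baseline start to ``margin_ms``
    before its end.  The matrix entry is the median correlation across
    trials; the diagonal is exactly 1.
    """
    if len(csd_trials) < 2:
        raise ValueError("need at least 2 trials for the correlation matrix")
    mats = []
    for trial in csd_trials:
        low = zero_phase_filter(trial.data, BASELINE_LOWPASS, trial.fs)
        b0, b1 = trial.epochs.baseline_ms
        sl = window_slice(trial.epochs, trial.fs,
                          (b0 + margin_ms, b1 - margin_ms))
        seg = low[:, sl]
        with np.errstate(invalid="ignore", divide="ignore"):
            mats.append(np.corrcoef(seg))
    corr = np.nanmedian(np.stack(mats), axis=0)
    np.fill_diagonal(corr, 1.0)
    return corr


def _block_contrast(corr: np.ndarray, split: int,
                    halfwidth: int | None = None) -> float:
    """Mean within-block minus mean between-block correlation (off-diagonal).

    With ``halfwidth`` the contrast is evaluated on the submatrix of the
    ``halfwidth`` channels on each side of the split only.  This keeps the
    measure local to the candidate border: a column has three laminar
    correlation blocks, and a global two-block contrast is drawn toward
    whichever domain boundary decorrelates most strongly rather than the
    one nearest the initial estimate.
    """
    n = corr.shape[0]
    if split <= 0 or split >= n:
        return -np.inf
    if halfwidth is not None:
        lo = max(split - halfwidth, 0)
        hi = min(split + halfwidth, n)
        corr = corr[lo:hi, lo:hi]
        split = split - lo
        n = corr.shape[0]
    mask = ~np.eye(n, dtype=bool)
    upper = np.zeros_like(mask)
    upper[:split, :split] = True
    lower = np.zeros_like(mask)
    lower[split:, split:] = True
    within = corr[(upper | lower) & mask]
    between = corr[~(upper | lower)]
    if within.size == 0 or between.size == 0:
        return -np.inf
    return float(within.mean() - between.mean())


def refine_border_from_correlation(corr: np.ndarray, initial_border_um: float,
                                   probe: ProbeGeometry,
                                   search_um: float = 200.0,
                                   local_halfwidth: int = 3) -> float:
    """Refine the border using the correlation matrix's block structure.

    Candidate borders are the midpoints between adjacent channels within
    ``+-search_um`` of the initial estimate; the candidate maximizing the
    local (mean within-block r) - (mean between-block r), evaluated on the
    ``local_halfwidth`` channels on each side of the split, wins.  Falls
    back to the initial border on ties.
    """
    depths = probe.depths_um
    best_border = float(initial_border_um)
    scores: list[tuple[float, float]] = []
    for split in range(1, probe.n_channels):
        mid = 0.5 * (depths[split - 1] + depths[split])
        if abs(mid - initial_border_um) > search_um:
            continue
        scores.append((_block_contrast(corr, split, local_halfwidth), mid))
    if not scores:
        return best_border
    top = max(s for s, _ in scores)
    winners = [mid for s, mid in scores if s == top]
    if len(winners) != 1 or not np.isfinite(top):
        return float(initial_border_um)
    return float(winners[0])


def assign_domains(border_um: float, probe: ProbeGeometry,
                   method: str = "polarity") -> LaminarAssignment:
    """Label every channel SG / G / IG relative to the layer-III/IV border.

    SG lies strictly above the border; G covers the border depth down to
    0.5 mm below it (channels exactly at the border belong to G); IG is
    everything deeper.
    """
    labels = []
    for depth in probe.depths_um:
        if depth < border_um:
            labels.append(Domain.SG)
        elif depth <= border_um + GRANULAR_THICKNESS_UM:
            labels.append(Domain.G)
        else:
            labels.append(Domain.IG)
    return LaminarAssignment(border_l3l4_um=float(border_um),
                             domains=tuple(labels), probe=probe,
                             method=method)
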