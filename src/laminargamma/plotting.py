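"""Quick-look figures for fitted results (matplotlib)."""

from __future__ import annotations

import numpy as np

from .laminar import Domain
from .session import Attention

__all__ = ["plot_power_profiles", "plot_phc_preference", "plot_evoked_csd"]

_DOMAIN_COLORS = {Domain.SG: "tab:red", Domain.G: "tab:blue",
                  Domain.IG: "tab:brown"}


def plot_power_profiles(results, ax=None):
    """Gamma-power depth profiles per condition with hotspot markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 5))
    depths = results.model.session.probe.depths_um
    for att, prof in results.power_profiles.items():
        ax.plot(prof, depths, label=att.value)
    for domain in Domain:
        h = results.hotspots[domain]
        if h.channel is not None:
            ax.axhline(depths[h.channel], ls=":", lw=0.8,
                       color=_DOMAIN_COLORS[domain])
    ax.axhline(results.border_um, color="k", ls="--", lw=1,
               label="III/IV border")
    ax.invert_yaxis()
    ax.set_xlabel("gamma power (corrected, a.u.)")
    ax.set_ylabel("depth (um)")
    ax.legend(fontsize=8)
    return ax


def plot_phc_preference(results, ax=None):
    """Normalized PhC preference of the three hotspots across depth."""
    import matplotlib.pyplot as plt

    if results.phc_preference is None:
        raise ValueError("no PhC preference in these results")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 5))
    depths = results.model.session.probe.depths_um
    for r, domain in enumerate(Domain):
        ax.plot(results.phc_preference[r], depths,
                color=_DOMAIN_COLORS[domain], label=f"{domain.value} hotspot")
    ax.axhline(results.border_um, color="k", ls="--", lw=1)
    ax.invert_yaxis()
    ax.set_xlabel("normalized gamma-PhC preference")
    ax.set_ylabel("depth (um)")
    ax.legend(fontsize=8)
    return ax


def plot_evoked_csd(results, ax=None):
    """Stimulus-onset CSD map used for layer identification."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    csd = results.evoked_csd
    depths = (csd.positions_um if csd.positions_um is not None
              else np.arange(csd.n_channels) * 100.0)
    vmax = np.max(np.abs(csd.data))
    im = ax.imshow(csd.data, aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax,
                   extent=[0, csd.n_samples, depths[-1], depths[0]])
    ax.axhline(results.border_um, color="k", ls="--", lw=1)
    ax.set_xlabel("time after stimulus onset (ms)")
    ax.set_ylabel("depth (um)")
    plt.colorbar(im, ax=ax, label="CSD (sink < 0)")
    return ax
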