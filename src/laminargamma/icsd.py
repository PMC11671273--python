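"""Spline inverse current source density (iCSD) for laminar probes.

The forward model assumes current sources evenly distributed over
cylindrical discs (radius ``R``) stacked along the column axis in an
isotropic medium of conductivity ``sigma``; the CSD varies smoothly with
depth as a natural cubic spline through the electrode depths, and is zero
beyond the end knots.  The potential contributed at depth offset ``dz`` by
a unit CSD x thickness element is

    k(dz) = (1 / (2 sigma)) * (sqrt(dz^2 + R^2) - |dz|).

Inversion solves the square forward matrix (spline basis integrated
against the kernel) per time sample; the resulting depth profiles are
optionally smoothed with a truncated, unit-sum Gaussian (SD 200 um in a
1,000 um window by default).

Units: with potentials in volts and depths converted to meters internally,
CSD comes out in A/m^3.  The simulator uses the same kernel, so forward /
inverse round trips are unit-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .session import CsdTrial, LfpTrial, ProbeGeometry, Session, window_slice

__all__ = [
    "ICsdParams",
    "ForwardMatrix",
    "disc_potential_kernel",
    "build_forward_matrix",
    "invert_spline_icsd",
    "smooth_depth_profile",
    "evoked_onset_csd",
]

_UM = 1e-6  # micrometers -> meters


@dataclass(frozen=True)
class ICsdParams:
    """Volume-conductor and smoothing parameters of the spline iCSD."""

    disc_radius_um: float = 500.0
    conductivity_S_per_m: float = 0.4
    smooth_sd_um: float = 200.0
    smooth_window_um: float = 1000.0
    boundary: str = "zero"  # CSD assumed zero beyond the end knots

    def __post_init__(self) -> None:
        for name in ("disc_radius_um", "conductivity_S_per_m",
                     "smooth_sd_um", "smooth_window_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.smooth_window_um < 2 * self.smooth_sd_um:
            raise ValueError("smoothing window must be at least 2 x SD")
        if self.boundary != "zero":
            raise ValueError("only the zero-outside boundary is implemented")


def disc_potential_kernel(dz_um: np.ndarray | float,
                          params: ICsdParams) -> np.ndarray | float:
    """Potential per unit (CSD x thickness) at depth offset ``dz_um``.

    Evaluates ``(1/(2 sigma)) (sqrt(dz^2 + R^2) - |dz|)`` in SI units
    (result in m^2/S, i.e. volts per (A/m^3 x m)).
    """
    dz = np.abs(np.asarray(dz_um, dtype=float)) * _UM
    r = params.disc_radius_um * _UM
    return (np.sqrt(dz * dz + r * r) - dz) / (2.0 * params.conductivity_S_per_m)


@dataclass(frozen=True)
class ForwardMatrix:
    """Square map from CSD values at the electrode-depth knots to potentials."""

    matrix: np.ndarray
    probe: ProbeGeometry
    params: ICsdParams

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def _spline_basis(depths_um: np.ndarray, k: int,
                  z_um: np.ndarray) -> np.ndarray:
    e = np.zeros(depths_um.size)
    e[k] = 1.0
    return CubicSpline(depths_um, e, bc_type="natural")(z_um)


def build_forward_matrix(probe: ProbeGeometry,
                         params: ICsdParams = ICsdParams(),
                         quad_step_um: float = 5.0) -> ForwardMatrix:
    """Integrate the disc kernel against the natural-spline CSD basis.

    ``F[j, k]`` is the potential at electrode ``j`` produced by the cubic
    spline that is 1 at knot ``k`` and 0 at every other knot (CSD zero
    beyond the end knots), computed on a fine quadrature grid.
    """
    depths = probe.depths_um
    if depths.size < 4:
        raise ValueError("spline iCSD needs at least 4 electrodes")
    z = np.arange(depths[0], depths[-1] + quad_step_um / 2.0, quad_step_um)
    dz_m = quad_step_um * _UM
    # kernel matrix: electrodes x quadrature points
    kern = disc_potential_kernel(depths[:, None] - z[None, :], params)
    basis = np.stack([_spline_basis(depths, k, z)
                      for k in range(depths.size)], axis=1)
    # trapezoid weights on the uniform grid
    w = np.full(z.size, dz_m)
    w[0] = w[-1] = dz_m / 2.0
    f = kern @ (basis * w[:, None])
    return ForwardMatrix(matrix=f, probe=probe, params=params)


def invert_spline_icsd(lfp: LfpTrial, fwd: ForwardMatrix) -> CsdTrial:
    """Solve ``F c = phi`` per time sample; CSD at the electrode depths."""
    if lfp.n_channels != fwd.matrix.shape[0]:
        raise ValueError("LFP channel count does not match forward matrix")
    csd = np.linalg.solve(fwd.matrix, lfp.data)
    return CsdTrial(data=csd, fs=lfp.fs, epochs=lfp.epochs,
                    condition=lfp.condition,
                    positions_um=fwd.probe.depths_um)


def _smoothing_matrix(positions_um: np.ndarray, params: ICsdParams) -> np.ndarray:
    d = positions_um[:, None] - positions_um[None, :]
    w = np.exp(-0.5 * (d / params.smooth_sd_um) ** 2)
    w[np.abs(d) > params.smooth_window_um / 2.0] = 0.0
    return w / w.sum(axis=1, keepdims=True)


def smooth_depth_profile(csd: CsdTrial,
                         params: ICsdParams = ICsdParams()) -> CsdTrial:
    """Gaussian-smooth each time sample along depth (unit-sum kernel).

    The kernel (SD 200 um) is truncated to half the finite window
    (+-500 um) and renormalized to unit sum, including at the edges, so a
    constant depth profile passes through unchanged.
    """
    if csd.n_channels < 2:
        raise ValueError("need at least 2 positions to smooth")
    pos = (csd.positions_um if csd.positions_um is not None
           else np.arange(csd.n_channels) * 100.0)
    sm = _smoothing_matrix(pos, params)
    return CsdTrial(data=sm @ csd.data, fs=csd.fs, epochs=csd.epochs,
                    condition=csd.condition, positions_um=pos)


def evoked_onset_csd(lfp_trials: list[LfpTrial], probe: ProbeGeometry,
                     params: ICsdParams = ICsdParams(),
                     fwd: ForwardMatrix | None = None,
                     window_ms: float = 250.0) -> CsdTrial:
    """Average stimulus-onset CSD map over the first ``window_ms`` ms.

    Averages the LFP of eligible trials (correct, stimulus in the RF) over
    the first 250 ms after stimulus onset across all attention conditions,
    then inverts and smooths.  Used for layer identification.
    """
    eligible = [t for t in lfp_trials
                if t.condition.rf_stim_present and t.condition.correct]
    if not eligible:
        raise ValueError("no eligible trials (correct, RF stimulus present)")
    if fwd is None:
        fwd = build_forward_matrix(probe, params)
    acc = None
    for t in eligible:
        onset = t.epochs.stim_onset_ms
        sl = window_slice(t.epochs, t.fs, (onset, onset + window_ms))
        seg = t.data[:, sl]
        acc = seg if acc is None else acc + seg
    mean_lfp = LfpTrial(data=acc / len(eligible), fs=eligible[0].fs,
                        epochs=eligible[0].epochs,
                        condition=eligible[0].condition)
    csd = invert_spline_icsd(mean_lfp, fwd)
    return smooth_depth_profile(csd, params)
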