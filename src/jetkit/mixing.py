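"""Mix-and-inject design calculations: dilution, flow focusing and diffusive mixing.

In a concentric-cones micromixer the sample stream is hydrodynamically
focused by a sheath (reactant) flow.  Under the plug-flow assumption (equal
axial velocity everywhere in the cross-section, justified by the centred
sample stream minimising Taylor dispersion) the focused inner-stream radius
follows the area partition

    r_inner = R * sqrt(q_sample / q_total),

and the sheath-to-sample flow-rate ratio (FRR) sets the dilution
(q_sheath + q_sample) / q_sample (a 10:1 FRR is an 11-fold dilution).

Reactant then reaches the sample core by radial diffusion.  The mixing time
is defined as the earliest time at which the centreline reactant
concentration reaches a threshold fraction (e.g. 12.5%) of the initial
sheath concentration.  The solver integrates

    dc/dt = D (1/r) d/dr (r dc/dr),   0 <= r <= R,

with zero-flux walls and the step initial condition c = 0 for r < r_inner,
c = c0 for r >= r_inner.  The problem is nondimensionalised with tau =
t D / R^2, so the R^2/D self-similarity (doubling D exactly halves the
mixing time) holds by construction.  Space is discretised with a
conservative cell-centred finite-volume scheme (cross-sectional reactant
mass is conserved to machine precision); time stepping is Crank-Nicolson
after a short backward-Euler start-up that damps the sharp initial
interface.

Channel lengths follow from plug flow: L = t * Q / (pi R^2), and the
residence time of a capillary extension between mixer and nozzle is its
volume divided by the total flow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import solve_banded

from ._units import UL_MIN_TO_M3_S

__all__ = [
    "MixerGeometry",
    "FlowRateRatio",
    "MixingProblem",
    "MixingResult",
    "MIXER_GEOMETRIES",
    "dilution_factor",
    "focused_stream_radius",
    "mixing_time",
    "channel_length_for_delay",
    "delay_for_capillary_extension",
]


@dataclass(frozen=True)
class MixerGeometry:
    """Micromixer channel geometry (um): mixing channel, main (sample) inlet,
    side (reactant) inlet and mixing-channel length."""

    d_channel_um: float
    d_main_um: float
    d_side_um: float
    l_channel_um: float

    def __post_init__(self) -> None:
        for name in ("d_channel_um", "d_main_um", "d_side_um", "l_channel_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def channel_radius_um(self) -> float:
        return self.d_channel_um / 2.0


#: Catalogued micromixer geometries (concentric-cones and Kenics-helix designs).
MIXER_GEOMETRIES: dict[str, MixerGeometry] = {
    "MVED_Y": MixerGeometry(100.0, 75.0, 180.0, 300.0),
    "MVED_Z": MixerGeometry(200.0, 100.0, 231.7, 300.0),
    "MVED_S": MixerGeometry(100.0, 75.0, 180.0, 2122.3),
    "MVED_V": MixerGeometry(100.0, 75.0, 180.0, 331.8),
    "JKMH_10": MixerGeometry(200.0, 100.0, 100.0, 950.0),
    "JKMH_10H": MixerGeometry(100.0, 50.0, 50.0, 950.0),
}


@dataclass(frozen=True)
class FlowRateRatio:
    """Sheath and sample volumetric flows (ul/min)."""

    q_sheath_ul_min: float
    q_sample_ul_min: float

    def __post_init__(self) -> None:
        if self.q_sample_ul_min <= 0:
            raise ValueError("q_sample must be positive")
        if self.q_sheath_ul_min < 0:
            raise ValueError("q_sheath must be non-negative")

    @property
    def q_total_ul_min(self) -> float:
        return self.q_sheath_ul_min + self.q_sample_ul_min

    @classmethod
    def from_string(cls, ratio: str, q_sample_ul_min: float = 1.0) -> "FlowRateRatio":
        """Build from a ratio string like ``"10:1"`` at a given sample flow."""
        sheath, sample = (float(tok) for tok in ratio.split(":"))
        return cls(q_sample_ul_min * sheath / sample, q_sample_ul_min)


def dilution_factor(frr: FlowRateRatio) -> float:
    """Fold-dilution of the sample after mixing: (q_sheath + q_sample)/q_sample."""
    return frr.q_total_ul_min / frr.q_sample_ul_min


def focused_stream_radius(frr: FlowRateRatio, channel_radius_um: float) -> float:
    """Radius (um) of the hydrodynamically focused sample stream.

    Plug-flow area partition: r_inner = R sqrt(q_sample/q_total).
    """
    if channel_radius_um <= 0:
        raise ValueError("channel radius must be positive")
    return channel_radius_um * math.sqrt(frr.q_sample_ul_min / frr.q_total_ul_min)


@dataclass
class MixingProblem:
    """Specification of a diffusive mixing computation.

    Defaults reflect the lysozyme/glucose design point: glucose diffusivity
    6.0e-10 m^2/s, 30 mM reactant against 3.5 mM protein binding sites, and a
    12.5% centreline threshold.
    """

    frr: FlowRateRatio
    channel_radius_um: float
    diffusivity_m2_s: float = 6.0e-10
    c_reactant_mM: float = 30.0
    c_protein_mM: float = 3.5
    threshold_fraction: float = 0.125
    q_total_ul_min: Optional[float] = None  # default: sheath + sample
    depletion: str = "none"  # "none" | "first_order_sink"
    sink_rate_s: float = 0.0  # first-order consumption rate in the sample core

    def __post_init__(self) -> None:
        if self.diffusivity_m2_s <= 0:
            raise ValueError("diffusivity must be positive")
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.channel_radius_um <= 0:
            raise ValueError("channel radius must be positive")
        if self.depletion not in ("none", "first_order_sink"):
            raise ValueError("depletion must be 'none' or 'first_order_sink'")
        if self.q_total_ul_min is None:
            self.q_total_ul_min = self.frr.q_total_ul_min


@dataclass
class MixingResult:
    t_mix_ms: float
    l_required_mm: float
    #: (tau, rho grid, concentration/c0) snapshots for diagnostics
    profile: list
    mass_drift: float  # max relative change of cross-sectional reactant mass


class ConvergenceWarning(UserWarning):
    """Grid refinement changed the mixing time by more than the stated tolerance."""


def _fv_operator(n: int, rho_inner: float, sink: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cell-centred FV discretisation of the dimensionless radial diffusion operator.

    Returns (lower, diag, upper) diagonals of A with (Ac)_i =
    [rho_{i+1/2}(c_{i+1}-c_i) - rho_{i-1/2}(c_i-c_{i-1})]/(rho_i h^2),
    plus the initial condition (partial-volume filled interface cell).
    """
    h = 1.0 / n
    rho = (np.arange(n) + 0.5) * h
    face = np.arange(1, n) * h  # interior faces; boundary fluxes are zero

    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    coeff = face / h**2
    diag[:-1] -= coeff / rho[:-1]
    upper[:-1] += coeff / rho[:-1]
    diag[1:] -= coeff / rho[1:]
    lower[1:] += coeff / rho[1:]

    if sink > 0:
        core = rho < rho_inner
        diag[core] -= sink

    # initial condition: fraction of each annular cell lying beyond rho_inner
    edges = np.arange(n + 1) * h
    lo, hi = edges[:-1], edges[1:]
    outer = np.clip(hi**2 - np.maximum(lo, rho_inner) ** 2, 0.0, None)
    c0 = np.where(hi <= rho_inner, 0.0, outer / (hi**2 - lo**2))
    return lower, diag, upper, c0


def _solve_dimensionless(
    rho_inner: float,
    threshold: float,
    n_nodes: int,
    sink: float,
    tau_max: float,
    n_snapshots: int = 5,
) -> tuple[float, list, float]:
    """March the dimensionless problem to the centreline threshold crossing.

    Returns (tau_mix, snapshots, mass_drift); tau_mix = nan if never crossed.
    """
    lower, diag, upper, c = _fv_operator(n_nodes, rho_inner, sink)
    h = 1.0 / n_nodes
    rho = (np.arange(n_nodes) + 0.5) * h
    mass0 = float(np.sum(rho * c))

    dtau = max(rho_inner**2, 4 * h**2) / 4000.0
    snapshots = [(0.0, rho.copy(), c.copy())]
    snap_interval = max(rho_inner**2, 4 * h**2)

    def banded(theta_dt: float) -> np.ndarray:
        ab = np.zeros((3, n_nodes))
        ab[0, 1:] = -theta_dt * upper[:-1]
        ab[1] = 1.0 - theta_dt * diag
        ab[2, :-1] = -theta_dt * lower[1:]
        return ab

    def apply_a(c: np.ndarray) -> np.ndarray:
        out = diag * c
        out[:-1] += upper[:-1] * c[1:]
        out[1:] += lower[1:] * c[:-1]
        return out

    tau = 0.0
    prev_center = c[0]
    mass_drift = 0.0
    # backward-Euler start-up (L-stable) damps the discontinuous initial profile
    be_steps = 50
    ab_be = banded(dtau / 4.0)
    ab_cn = banded(dtau / 2.0)
    step = 0
    while tau < tau_max:
        if step < be_steps:
            c = solve_banded((1, 1), ab_be, c)
            tau += dtau / 4.0
        else:
            rhs = c + (dtau / 2.0) * apply_a(c)
            c = solve_banded((1, 1), ab_cn, rhs)
            tau += dtau
        step += 1
        if sink == 0:
            mass_drift = max(mass_drift, abs(float(np.sum(rho * c)) / mass0 - 1.0))
        if len(snapshots) < n_snapshots and tau >= len(snapshots) * snap_interval:
            snapshots.append((tau, rho.copy(), c.copy()))
        if c[0] >= threshold:
            dt_last = dtau / 4.0 if step <= be_steps else dtau
            frac = (c[0] - threshold) / max(c[0] - prev_center, 1e-300)
            tau_mix = tau - dt_last * min(frac, 1.0)
            snapshots.append((tau, rho.copy(), c.copy()))
            return tau_mix, snapshots, mass_drift
        prev_center = c[0]
    return math.nan, snapshots, mass_drift


def mixing_time(
    problem: MixingProblem,
    n_nodes: int = 400,
    *,
    convergence_check: bool = True,
    tau_max: float = 6.0,
) -> MixingResult:
    """Diffusive mixing time (ms) to the centreline threshold, plus channel length.

    Solves the radial diffusion problem described in the module docstring.
    With ``convergence_check`` the solve is repeated on a doubled grid and a
    :class:`ConvergenceWarning` is raised if the mixing time moves by more
    than 0.5%.  Raises ``ValueError("threshold unreachable")`` when the
    requested threshold exceeds the equilibrium centreline fraction.
    """
    rho_inner = focused_stream_radius(problem.frr, problem.channel_radius_um) / (
        problem.channel_radius_um
    )
    thr = problem.threshold_fraction
    equilibrium = 1.0 - rho_inner**2
    if problem.depletion == "none" and thr >= equilibrium:
        raise ValueError(
            f"threshold unreachable: centreline equilibrium fraction is {equilibrium:.4f}"
        )
    sink = 0.0
    if problem.depletion == "first_order_sink":
        # nondimensionalise the first-order consumption rate with R^2/D
        sink = problem.sink_rate_s * (problem.channel_radius_um * 1e-6) ** 2 / (
            problem.diffusivity_m2_s
        )

    tau_mix, snapshots, drift = _solve_dimensionless(rho_inner, thr, n_nodes, sink, tau_max)
    if math.isnan(tau_mix):
        raise ValueError("threshold unreachable within the integration horizon")
    if convergence_check:
        tau_fine, _, _ = _solve_dimensionless(rho_inner, thr, 2 * n_nodes, sink, tau_max)
        if abs(tau_fine / tau_mix - 1.0) > 0.005:
            warnings.warn(
                f"mixing_time changed by {abs(tau_fine / tau_mix - 1):.2%} on grid "
                "doubling; increase n_nodes",
                ConvergenceWarning,
                stacklevel=2,
            )

    scale_s = (problem.channel_radius_um * 1e-6) ** 2 / problem.diffusivity_m2_s
    t_ms = tau_mix * scale_s * 1e3
    l_mm = channel_length_for_delay(t_ms, problem.q_total_ul_min, problem.channel_radius_um)
    return MixingResult(t_mix_ms=t_ms, l_required_mm=l_mm, profile=snapshots, mass_drift=drift)


def channel_length_for_delay(
    t_ms: float, q_total_ul_min: float, channel_radius_um: float
) -> float:
    """Channel length (mm) realising a delay under plug flow: L = t Q/(pi R^2)."""
    if t_ms < 0 or q_total_ul_min <= 0 or channel_radius_um <= 0:
        raise ValueError("inputs must be positive (delay may be zero)")
    v_mean = q_total_ul_min * UL_MIN_TO_M3_S / (math.pi * (channel_radius_um * 1e-6) ** 2)
    return t_ms * 1e-3 * v_mean * 1e3


def delay_for_capillary_extension(
    l_extension_mm: float, q_total_ul_min: float, inner_diameter_um: float
) -> float:
    """Residence time (ms) of a capillary extension: volume / total flow."""
    if l_extension_mm < 0 or q_total_ul_min <= 0 or inner_diameter_um <= 0:
        raise ValueError("inputs must be positive (length may be zero)")
    volume_m3 = l_extension_mm * 1e-3 * math.pi * (inner_diameter_um * 1e-6 / 2.0) ** 2
    return volume_m3 / (q_total_ul_min * UL_MIN_TO_M3_S) * 1e3
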