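"""Electrospray (cone-jet) droplet-size analysis.

Aerosolised sample delivery for single-particle imaging produces droplets by
the break-up of an electrospray jet at the apex of a Taylor cone.  Droplet
diameters measured by a differential mobility analyser (DMA) as dried
residue sizes are converted back to initial droplet diameters with the
involatile-solute calibration D = D_residue / c^(1/3) (c the solute volume
fraction, e.g. sucrose at c = 0.05).

Results taken at different liquid conductivities K collapse onto a single
curve in the dimensionless coordinates

    Q/Q_sigma = Q K rho / (sigma eps0),
    D/D_sigma = D [K^2 rho / (sigma eps0^2)]^(1/3),

with rho the liquid density, sigma its surface tension and eps0 the vacuum
permittivity.  Below Q/Q_sigma = 1000 the diameter follows the cone-jet
D ~ Q^(1/3) law; above it the scaling steepens (classified here, not
fitted).  Since sample particles partition into droplets in proportion to
droplet volume, the representative diameter is the mode of the
volume-weighted (D^3-weighted) size distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._units import EPSILON_0, NL_MIN_TO_M3_S

__all__ = [
    "ElectrosprayConditions",
    "SizeDistribution",
    "DimensionlessPoint",
    "droplet_from_residue",
    "dimensionless_flow",
    "dimensionless_diameter",
    "diameter_from_dimensionless",
    "classify_regime",
    "volume_weighted_mode",
    "read_trace",
    "CONE_JET_REGIME_LIMIT",
]

#: Dimensionless flow above which the cone-jet Q^(1/3) scaling no longer holds.
CONE_JET_REGIME_LIMIT = 1000.0


@dataclass(frozen=True)
class ElectrosprayConditions:
    """Liquid feed and properties: flow (nl/min), conductivity (S/m),
    density (kg/m^3) and surface tension (N/m).  Defaults are aqueous."""

    q_nl_min: float
    conductivity_S_m: float
    density_kg_m3: float = 1000.0
    surface_tension_N_m: float = 0.072

    def __post_init__(self) -> None:
        for name in ("q_nl_min", "conductivity_S_m", "density_kg_m3", "surface_tension_N_m"):
            if getattr(self, name) < 0 or (name != "q_nl_min" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SizeDistribution:
    """A DMA-style number-weighted size trace: bin diameters (nm) and counts."""

    bin_diameters_nm: Sequence[float]
    number_concentrations: Sequence[float]

    def __post_init__(self) -> None:
        d = np.asarray(self.bin_diameters_nm, dtype=float)
        n = np.asarray(self.number_concentrations, dtype=float)
        if d.shape != n.shape or d.ndim != 1 or d.size == 0:
            raise ValueError("diameters and concentrations must be equal-length 1-D")
        if not np.all(np.diff(d) > 0):
            raise ValueError("bin diameters must be strictly increasing")
        if np.any(n < 0):
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class DimensionlessPoint:
    q_star: float
    d_star: float

    def __post_init__(self) -> None:
        if self.q_star <= 0 or self.d_star <= 0:
            raise ValueError("dimensionless coordinates must be positive")


def droplet_from_residue(d_residue: float, volume_fraction: float) -> float:
    """Initial droplet diameter from the dried-residue diameter.

    D = D_residue / c^(1/3); units follow the input.  Valid for
    0 < c <= 1 (c = 1 is the identity)."""
    if not 0 < volume_fraction <= 1:
        raise ValueError("volume_fraction must lie in (0, 1]")
    return d_residue / volume_fraction ** (1.0 / 3.0)


def dimensionless_flow(cond: ElectrosprayConditions) -> float:
    """Q/Q_sigma = Q K rho / (sigma eps0), with Q converted to m^3/s."""
    q_si = cond.q_nl_min * NL_MIN_TO_M3_S
    return q_si * cond.conductivity_S_m * cond.density_kg_m3 / (
        cond.surface_tension_N_m * EPSILON_0
    )


def _diameter_scale(cond: ElectrosprayConditions) -> float:
    # [K^2 rho / (sigma eps0^2)]^(1/3), in 1/m
    return (
        cond.conductivity_S_m**2
        * cond.density_kg_m3
        / (cond.surface_tension_N_m * EPSILON_0**2)
    ) ** (1.0 / 3.0)


def dimensionless_diameter(d_nm: float, cond: ElectrosprayConditions) -> float:
    """D/D_sigma = D [K^2 rho / (sigma eps0^2)]^(1/3), D supplied in nm."""
    if d_nm <= 0:
        raise ValueError("diameter must be positive")
    return d_nm * 1e-9 * _diameter_scale(cond)


def diameter_from_dimensionless(d_star: float, cond: ElectrosprayConditions) -> float:
    """Inverse of :func:`dimensionless_diameter`: physical diameter in nm."""
    if d_star <= 0:
        raise ValueError("d_star must be positive")
    return d_star / _diameter_scale(cond) * 1e9


def classify_regime(point: DimensionlessPoint) -> str:
    """``"cone_jet_Q13"`` strictly below Q/Q_sigma = 1000, else ``"super_threshold"``."""
    return "cone_jet_Q13" if point.q_star < CONE_JET_REGIME_LIMIT else "super_threshold"


def volume_weighted_mode(dist: SizeDistribution) -> float:
    """Bin diameter (nm) with the largest volume-weighted concentration D^3 n(D)."""
    d = np.asarray(dist.bin_diameters_nm, dtype=float)
    n = np.asarray(dist.number_concentrations, dtype=float)
    if not np.any(n > 0):
        raise ValueError("distribution has no positive concentrations")
    return float(d[np.argmax(d**3 * n)])


def read_trace(path: str | Path) -> SizeDistribution:
    """Read a two-column CSV trace (diameter_nm, number_conc)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("trace must have two columns: diameter_nm, number_conc")
    return SizeDistribution(
        df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
    )
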