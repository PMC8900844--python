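"""Empirical gas-dynamic-virtual-nozzle (GDVN) jet velocity and diameter model.

Gas-focused liquid microjets follow, to good accuracy, the pressure-drop
scaling v ~ (dP)^(1/2) with dP approximated by Q_g / D^2, where Q_g is the
helium mass flow and D the gas-aperture diameter.  Measured jet velocities
additionally show a liquid-flow dependence, captured empirically by

    v_jet = a + b * (Q_g / D^2)^(1/2) / Q_l^(1/4)

with a = 8.35 and b = 1022 when Q_g is given in mg/min, D in um, Q_l in
ul/min and v in m/s.  The Q_l^(-1/4) factor has no known physical
derivation; the constants are empirical and valid only inside the measured
flow/geometry envelope (in-vacuum jetting).  Combined with volume
conservation, d_jet = [4 Q_l / (pi v)]^(1/2), the model implies
d_jet ~ Q_l^(5/8) / (Q_g/D^2)^(1/4) whenever the offset a is negligible.

This module provides forward prediction, least-squares refitting of (a, b)
against measured (Q_l, Q_g, D, v) tables, the pressure-drop proxy, and the
plug-flow stream velocity of high-viscosity extrusion (HVE) capillaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from ._units import UL_MIN_TO_M3_S

__all__ = [
    "NozzleGeometry",
    "FlowConditions",
    "ScalingCoefficients",
    "JetPrediction",
    "ScalingLawFit",
    "ExtrapolationWarning",
    "DEFAULT_COEFFICIENTS",
    "ATMOSPHERIC_VELOCITY_FACTOR",
    "predict_jet_velocity",
    "jet_diameter",
    "fit_scaling_law",
    "pressure_drop_proxy",
    "hve_stream_velocity",
    "predict",
]

#: Flow/geometry envelope actually covered by the in-vacuum measurements.
#: Outside it the scaling law extrapolates and a warning is issued.
QL_ENVELOPE_UL_MIN = (5.0, 100.0)
QG_ENVELOPE_MG_MIN = (10.0, 40.0)
D_ENVELOPE_UM = (30.0, 145.0)

#: Jetting into an atmospheric chamber yields roughly five-fold faster jets
#: than the same nozzle in vacuum; exposed as an opt-in multiplier.
ATMOSPHERIC_VELOCITY_FACTOR = 5.0

NOZZLE_FAMILIES = ("GDVN", "DFFN", "HVE", "mixing-GDVN", "CCT")


class ExtrapolationWarning(UserWarning):
    """Inputs fall outside the measured envelope of the empirical scaling law."""


@dataclass(frozen=True)
class NozzleGeometry:
    """Nozzle orifice geometry: liquid aperture, gas aperture and their spacing (um)."""

    d_liquid_um: float
    d_gas_um: float
    h_liquid_gas_um: float
    family: str = "GDVN"
    design_name: str = ""

    def __post_init__(self) -> None:
        for name in ("d_liquid_um", "d_gas_um", "h_liquid_gas_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.family not in NOZZLE_FAMILIES:
            raise ValueError(f"family must be one of {NOZZLE_FAMILIES}")


@dataclass(frozen=True)
class FlowConditions:
    """Liquid volumetric flow (ul/min) and sheath-gas mass flow (mg/min)."""

    q_liquid_ul_min: float
    q_gas_mg_min: float

    def __post_init__(self) -> None:
        if self.q_liquid_ul_min < 0 or self.q_gas_mg_min < 0:
            raise ValueError("flow rates must be non-negative")


@dataclass(frozen=True)
class ScalingCoefficients:
    """Coefficients (a, b) of the empirical velocity scaling law.

    The unit contract is fixed: Q_g in mg/min, D in um, Q_l in ul/min
    yield v in m/s.  ``a`` is a velocity offset, ``b`` a scale factor.
    """

    a: float = 8.35
    b: float = 1022.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be positive")


DEFAULT_COEFFICIENTS = ScalingCoefficients()


@dataclass(frozen=True)
class JetPrediction:
    velocity_m_s: float
    diameter_um: float
    pressure_drop_proxy: float  # Q_g / D^2, mg/min/um^2


@dataclass(frozen=True)
class ScalingLawFit:
    """Least-squares fit result for the velocity scaling law."""

    coefficients: ScalingCoefficients
    stderr_a: float
    stderr_b: float
    rmse: float
    r_squared: float
    n: int


def _scaling_predictor(q_gas: float, d_gas: float, q_liquid: float) -> float:
    return math.sqrt(q_gas / d_gas**2) / q_liquid**0.25


def _check_envelope(flow: FlowConditions, nozzle: NozzleGeometry) -> None:
    out = []
    if not QL_ENVELOPE_UL_MIN[0] <= flow.q_liquid_ul_min <= QL_ENVELOPE_UL_MIN[1]:
        out.append(f"Q_l={flow.q_liquid_ul_min} ul/min outside {QL_ENVELOPE_UL_MIN}")
    if not QG_ENVELOPE_MG_MIN[0] <= flow.q_gas_mg_min <= QG_ENVELOPE_MG_MIN[1]:
        out.append(f"Q_g={flow.q_gas_mg_min} mg/min outside {QG_ENVELOPE_MG_MIN}")
    if not D_ENVELOPE_UM[0] <= nozzle.d_gas_um <= D_ENVELOPE_UM[1]:
        out.append(f"D={nozzle.d_gas_um} um outside {D_ENVELOPE_UM}")
    if out:
        warnings.warn(
            "scaling law extrapolated beyond measured envelope: " + "; ".join(out),
            ExtrapolationWarning,
            stacklevel=3,
        )


def predict_jet_velocity(
    flow: FlowConditions,
    nozzle: NozzleGeometry,
    coeffs: ScalingCoefficients = DEFAULT_COEFFICIENTS,
    *,
    atmospheric: bool = False,
) -> float:
    """Predict the in-vacuum jet velocity (m/s) from flows and gas aperture.

    Evaluates v = a + b (Q_g/D^2)^(1/2) / Q_l^(1/4).  Inputs outside the
    measured envelope trigger an :class:`ExtrapolationWarning` but are never
    refused.  ``atmospheric=True`` applies the empirical five-fold speed-up
    observed when jetting into an atmospheric-pressure chamber.
    """
    if flow.q_liquid_ul_min == 0:
        raise ValueError("scaling law undefined at zero liquid flow")
    _check_envelope(flow, nozzle)
    v = coeffs.a + coeffs.b * _scaling_predictor(
        flow.q_gas_mg_min, nozzle.d_gas_um, flow.q_liquid_ul_min
    )
    if atmospheric:
        v *= ATMOSPHERIC_VELOCITY_FACTOR
    return v


def jet_diameter(q_liquid_ul_min: float, velocity_m_s: float) -> float:
    """Jet diameter (um) from volume conservation, d = [4 Q_l / (pi v)]^(1/2)."""
    if velocity_m_s <= 0:
        raise ValueError("velocity must be positive")
    if q_liquid_ul_min < 0:
        raise ValueError("liquid flow must be non-negative")
    q_si = q_liquid_ul_min * UL_MIN_TO_M3_S
    return math.sqrt(4.0 * q_si / (math.pi * velocity_m_s)) * 1e6


def pressure_drop_proxy(flow: FlowConditions, nozzle: NozzleGeometry) -> float:
    """Meniscus pressure-drop proxy Q_g / D^2 (mg/min/um^2)."""
    return flow.q_gas_mg_min / nozzle.d_gas_um**2


def predict(
    flow: FlowConditions,
    nozzle: NozzleGeometry,
    coeffs: ScalingCoefficients = DEFAULT_COEFFICIENTS,
    *,
    atmospheric: bool = False,
) -> JetPrediction:
    """Convenience wrapper returning velocity, diameter and pressure proxy together."""
    v = predict_jet_velocity(flow, nozzle, coeffs, atmospheric=atmospheric)
    return JetPrediction(
        velocity_m_s=v,
        diameter_um=jet_diameter(flow.q_liquid_ul_min, v),
        pressure_drop_proxy=pressure_drop_proxy(flow, nozzle),
    )


def fit_scaling_law(data: pd.DataFrame | Iterable) -> ScalingLawFit:
    """Refit (a, b) by ordinary least squares of v on x = (Q_g/D^2)^(1/2)/Q_l^(1/4).

    ``data`` is a DataFrame (or anything convertible) with columns
    ``q_liquid_ul_min``, ``q_gas_mg_min``, ``d_gas_um``, ``v_m_s``.
    The regression is unweighted on untransformed velocities.
    """
    df = pd.DataFrame(data)
    required = ["q_liquid_ul_min", "q_gas_mg_min", "d_gas_um", "v_m_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if len(df) < 3:
        raise ValueError("at least 3 measurements are required")
    if (df["q_liquid_ul_min"] <= 0).any() or (df["q_gas_mg_min"] <= 0).any() or (
        df["d_gas_um"] <= 0
    ).any():
        raise ValueError("flows and diameters must be positive")

    x = np.sqrt(df["q_gas_mg_min"] / df["d_gas_um"] ** 2) / df["q_liquid_ul_min"] ** 0.25
    v = df["v_m_s"].to_numpy(float)
    if np.ptp(x.to_numpy(float)) == 0:
        raise ValueError("degenerate design: all predictor values identical")

    res = stats.linregress(x, v)
    resid = v - (res.intercept + res.slope * x.to_numpy(float))
    return ScalingLawFit(
        coefficients=ScalingCoefficients(a=res.intercept, b=res.slope),
        stderr_a=res.intercept_stderr,
        stderr_b=res.stderr,
        rmse=float(np.sqrt(np.mean(resid**2))),
        r_squared=float(res.rvalue**2),
        n=len(df),
    )


def hve_stream_velocity(q_liquid_ul_min: float, inner_diameter_um: float) -> float:
    """Plug-flow stream velocity (mm/s) of a high-viscosity extrusion capillary.

    v = Q / (pi ID^2 / 4).  HVE runs at 0.05-2.0 ul/min; through a 100 um ID
    capillary this spans roughly 0.1-4.2 mm/s.
    """
    if inner_diameter_um <= 0:
        raise ValueError("inner diameter must be positive")
    if q_liquid_ul_min < 0:
        raise ValueError("liquid flow must be non-negative")
    area_m2 = math.pi * (inner_diameter_um * 1e-6) ** 2 / 4.0
    return q_liquid_ul_min * UL_MIN_TO_M3_S / area_m2 * 1e3
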