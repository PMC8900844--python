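"""Serial-crystallography acquisition planning and device selection.

Structure determination by serial femtosecond crystallography aggregates
indexed diffraction patterns one pulse at a time.  The acquisition time for
a target number of indexed patterns follows directly from the pulse budget:

    t = N_indexed / (hit_rate * indexing_rate * pulses_per_second),

e.g. 5000 indexed patterns at a 1% hit rate, 50% indexing rate and 3520
pulses/s take about 5 minutes; a highly redundant 30000-pattern set about
30 minutes.  Data quality improves with the square root of the number of
patterns, so quadrupling patterns doubles quality.

The module also ships the facility's injection-device catalog (GDVNs,
micromixers, mixing-GDVNs, DFFNs, high-viscosity extruders and electrospray
tips) with their minimum liquid flows and compatible pulse modes, and
filters it against a pulse pattern and available sample flow.  HVE-class
devices move the sample so slowly that only single-pulse 10 Hz trains are
compatible.  The sample-chamber vacuum limit for detector operation
(2e-4 mbar) is retained as an advisory constant only.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .timing import PulsePattern

__all__ = [
    "AcquisitionParams",
    "DeviceRecord",
    "ReplenishmentCheck",
    "CHAMBER_PRESSURE_LIMIT_MBAR",
    "acquisition_time",
    "format_acquisition_time",
    "relative_quality",
    "load_catalog",
    "save_catalog",
    "catalog_to_dataframe",
    "select_devices",
    "check_replenishment",
]

#: Advisory upper bound on sample-chamber pressure for detector operation.
CHAMBER_PRESSURE_LIMIT_MBAR = 2e-4

#: Mapping of catalog pulse-mode labels to the exact intra-train rates (Hz)
#: they denote.  The printed labels are rounded; the underlying modes are
#: defined by their inter-pulse spacings (see :mod:`jetkit.timing`).
_PULSE_MODE_RATES: dict[str, Optional[float]] = {
    "<=4.5 MHz": 1e9 / 221.6,
    "<=2.3 MHz": 1e9 / 443.3,
    "<=1.1 MHz": 1e9 / 886.5,
    "<=0.5 MHz": 1e9 / 1773.0,
    "<=0.14 MHz": 1e9 / 886.5 / 8.0,
    "10 Hz": None,  # single-pulse trains only
    "depends": None,  # limited by the attached nozzle, not the mixer
}


@dataclass(frozen=True)
class AcquisitionParams:
    n_indexed_target: int
    hit_rate: float
    indexing_rate: float
    pulses_per_second: float

    def __post_init__(self) -> None:
        if self.n_indexed_target < 1:
            raise ValueError("n_indexed_target must be >= 1")
        for name in ("hit_rate", "indexing_rate"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.pulses_per_second <= 0:
            raise ValueError("pulses_per_second must be positive")


@dataclass(frozen=True)
class DeviceRecord:
    """One catalog entry; ``geometry`` is the catalogued parameter string (um)."""

    device_type: str
    design_name: str
    geometry: str
    q_liquid_min_ul_min: float
    pulse_mode: str
    q_liquid_max_ul_min: Optional[float] = None
    requires_sheath_liquid: bool = False
    sheath_min_ul_min: Optional[float] = None

    @property
    def max_intra_train_rate_hz(self) -> Optional[float]:
        """Maximum compatible intra-train rate; None if unconstrained/single-pulse."""
        return _PULSE_MODE_RATES.get(self.pulse_mode)

    @property
    def single_pulse_only(self) -> bool:
        """True for HVE-class records: one pulse per 10 Hz train at most."""
        return self.pulse_mode == "10 Hz"


@dataclass(frozen=True)
class ReplenishmentCheck:
    ok: bool
    margin_m_s: float


def acquisition_time(params: AcquisitionParams) -> float:
    """Estimated acquisition time in seconds for the target indexed-pattern count."""
    return params.n_indexed_target / (
        params.hit_rate * params.indexing_rate * params.pulses_per_second
    )


def format_acquisition_time(seconds: float) -> str:
    """Human-readable minutes: nearest minute below 10 min, one significant
    figure at or above (284 s -> "5 min", 1705 s -> "30 min")."""
    minutes = seconds / 60.0
    if minutes < 10:
        return f"{max(round(minutes), 1)} min"
    magnitude = 10 ** math.floor(math.log10(minutes))
    return f"{round(minutes / magnitude) * magnitude:g} min"


def relative_quality(n1: int, n2: int) -> float:
    """Data-quality ratio between pattern counts: sqrt(n1/n2)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("pattern counts must be >= 1")
    return math.sqrt(n1 / n2)


def _records_from_frame(df: pd.DataFrame) -> list[DeviceRecord]:
    records = []
    for row in df.to_dict("records"):
        qmax = row.get("q_liquid_max_ul_min")
        sheath_min = row.get("sheath_min_ul_min")
        requires = row.get("requires_sheath_liquid", False)
        if isinstance(requires, str):
            requires = requires.strip().lower() == "true"
        records.append(
            DeviceRecord(
                device_type=str(row["device_type"]),
                design_name=str(row["design_name"]),
                geometry=str(row["geometry"]),
                q_liquid_min_ul_min=float(row["q_liquid_min_ul_min"]),
                pulse_mode=str(row["pulse_mode"]),
                q_liquid_max_ul_min=None if pd.isna(qmax) else float(qmax),
                requires_sheath_liquid=bool(requires),
                sheath_min_ul_min=None if pd.isna(sheath_min) else float(sheath_min),
            )
        )
    return records


def load_catalog(path: str | Path | None = None) -> list[DeviceRecord]:
    """Load the device catalog (the bundled one by default; CSV or JSON)."""
    if path is None:
        with resources.files("jetkit.data").joinpath("device_catalog.csv").open() as fh:
            return _records_from_frame(pd.read_csv(fh))
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    return _records_from_frame(df)


def catalog_to_dataframe(catalog: Sequence[DeviceRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in catalog])


def save_catalog(catalog: Sequence[DeviceRecord], path: str | Path) -> None:
    """Serialise the catalog as CSV or JSON (by extension) with identical content."""
    path = Path(path)
    df = catalog_to_dataframe(catalog)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.to_dict("records"), indent=1))
    else:
        df.to_csv(path, index=False)


def select_devices(
    catalog: Sequence[DeviceRecord],
    pattern: PulsePattern,
    q_liquid_ul_min: float,
) -> list[DeviceRecord]:
    """Catalog records compatible with a pulse pattern and available sample flow.

    A record is kept when the offered flow meets its minimum and the
    pattern's intra-train rate does not exceed its rated maximum (a small
    relative tolerance absorbs label rounding).  Single-pulse-only records
    (HVE class) require trains of at most one pulse.  Upper flow bounds are
    informational and not enforced.
    """
    if q_liquid_ul_min < 0:
        raise ValueError("q_liquid must be non-negative")
    out = []
    for rec in catalog:
        if q_liquid_ul_min < rec.q_liquid_min_ul_min:
            continue
        if rec.single_pulse_only:
            if pattern.pulses_per_train > 1:
                continue
        else:
            max_rate = rec.max_intra_train_rate_hz
            if max_rate is not None and pattern.intra_train_rate_hz > max_rate * (1 + 1e-9):
                continue
        out.append(rec)
    return out


def check_replenishment(predicted_v_m_s: float, required_v_m_s: float) -> ReplenishmentCheck:
    """Is the predicted jet velocity sufficient for the required replenishment?"""
    if predicted_v_m_s < 0 or required_v_m_s < 0:
        raise ValueError("velocities must be non-negative")
    return ReplenishmentCheck(
        ok=predicted_v_m_s >= required_v_m_s,
        margin_m_s=predicted_v_m_s - required_v_m_s,
    )
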