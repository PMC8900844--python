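"""Seeded synthetic-data generators with machine-readable ground truth.

Every input class the toolkit consumes can be generated here with known
ground truth, so the full pipeline is testable without experimental data:

* gap-train jet micrographs (periodic X-ray explosion gaps),
* double-exposure droplet micrographs (dual-pulse imaging),
* jet-velocity measurement tables following the empirical scaling law,
* lognormal DMA-style droplet size traces,
* an independent fine-grid explicit-Euler reference for the mixing solver.

Image geometry defaults emulate the in-chamber side-view microscope
(1075 x 310 px, ~0.65 um/px).  The noise model is additive Gaussian after a
Gaussian blur; all randomness flows through a mandatory integer seed and
regeneration is bit-identical.  Droplet axial positions keep a minimum
separation of three droplet diameters so autocorrelation pairing stays
unambiguous; a displacement exceeding that separation triggers a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.ndimage import gaussian_filter

from .electrospray import SizeDistribution
from .jet_model import ScalingCoefficients
from .mixing import MixingProblem, focused_stream_radius
from .timing import PulsePattern
from .velocimetry import JetImage

__all__ = [
    "GeneratorSpec",
    "gen_gap_image",
    "gen_double_exposure_image",
    "gen_velocity_dataset",
    "gen_droplet_trace",
    "gen_mixing_reference",
]

_BACKGROUND = 0.1
_FOREGROUND = 1.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Common image-generation parameters; the seed is mandatory."""

    seed: int
    noise_level: float = 0.05
    pixel_size_um: float = 0.65
    image_shape: tuple[int, int] = (310, 1075)  # (height, width)

    def __post_init__(self) -> None:
        if not 0 <= self.noise_level < 1:
            raise ValueError("noise_level must lie in [0, 1)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


def _band_rows(height: int, width_px: float) -> np.ndarray:
    """Transverse (row) coverage profile of a jet band centred in the image."""
    centre = (height - 1) / 2.0
    rows = np.arange(height)
    return np.clip(width_px / 2.0 - np.abs(rows - centre) + 0.5, 0.0, 1.0)


def gen_gap_image(
    v_m_s: float,
    pattern: PulsePattern,
    jet_width_um: float,
    spec: GeneratorSpec,
    gap_length_um: float = 25.0,
) -> tuple[JetImage, np.ndarray]:
    """Synthetic gap-train micrograph plus ground-truth gap midpoints (um).

    A bright jet band runs horizontally; dark gaps recur at the spacing
    v / f set by the pulse pattern, with a seeded random phase.  Gap edges
    are rendered with sub-pixel coverage so the true midpoints are exact.
    """
    if v_m_s <= 0:
        raise ValueError("velocity must be positive")
    height, width = spec.image_shape
    spacing_um = v_m_s / pattern.intra_train_rate_hz * 1e6
    spacing_px = spacing_um / spec.pixel_size_um
    if spacing_px < 2:
        raise ValueError("unresolvable: gap spacing below 2 pixels")
    gap_px = gap_length_um / spec.pixel_size_um
    if gap_px >= spacing_px:
        raise ValueError("gap length must be smaller than the gap spacing")

    rng = np.random.default_rng(spec.seed)
    phase_px = rng.uniform(0, spacing_px)

    # liquid coverage along the jet axis (1 = liquid, 0 = gap), anti-aliased
    x = np.arange(width)
    coverage = np.ones(width)
    centres = []
    c = phase_px
    while c < width:
        lo, hi = c - gap_px / 2.0, c + gap_px / 2.0
        overlap = np.clip(np.minimum(hi, x + 1.0) - np.maximum(lo, x), 0.0, 1.0)
        coverage -= overlap
        if lo > 1.0 and hi < width - 1.0:  # fully interior gap -> ground truth
            centres.append(c)
        c += spacing_px
    coverage = np.clip(coverage, 0.0, 1.0)

    band = _band_rows(height, jet_width_um / spec.pixel_size_um)
    img = _BACKGROUND + (_FOREGROUND - _BACKGROUND) * np.outer(band, coverage)
    img = gaussian_filter(img, sigma=1.0)
    img += rng.normal(0.0, spec.noise_level * (_FOREGROUND - _BACKGROUND), img.shape)

    image = JetImage(img, spec.pixel_size_um, jet_axis="horizontal", modality="gap_train")
    return image, np.asarray(centres) * spec.pixel_size_um


def gen_double_exposure_image(
    v_m_s: float,
    delay_ns: float,
    droplet_diameter_um: float,
    n_droplets: int,
    spec: GeneratorSpec,
) -> tuple[JetImage, float]:
    """Synthetic double-exposure droplet micrograph plus the true pair offset (um).

    ``n_droplets`` droplets are placed at seeded random axial positions with a
    minimum separation of three droplet diameters; each appears twice,
    offset by dx = v * dt along the flow direction.
    """
    if v_m_s <= 0 or delay_ns <= 0:
        raise ValueError("velocity and delay must be positive")
    height, width = spec.image_shape
    dx_um = v_m_s * delay_ns * 1e-9 * 1e6
    dx_px = dx_um / spec.pixel_size_um
    if dx_px < 1:
        raise ValueError("pair displacement below 1 pixel")
    min_sep_um = 3.0 * droplet_diameter_um
    if dx_um > min_sep_um:
        warnings.warn(
            "pair displacement exceeds the minimum droplet separation; "
            "autocorrelation pairing may be ambiguous",
            UserWarning,
            stacklevel=2,
        )

    rng = np.random.default_rng(spec.seed)
    r_px = droplet_diameter_um / spec.pixel_size_um / 2.0
    min_sep_px = min_sep_um / spec.pixel_size_um
    margin = r_px + 2.0
    x_max = width - margin - dx_px

    positions: list[float] = []
    attempts = 0
    while len(positions) < n_droplets and attempts < 20000:
        cand = rng.uniform(margin, x_max)
        if all(abs(cand - p) >= min_sep_px for p in positions):
            positions.append(cand)
        attempts += 1
    if len(positions) < n_droplets:
        raise ValueError("could not place droplets with the required separation")

    img = np.full((height, width), _BACKGROUND)
    y0 = (height - 1) / 2.0
    pad = int(math.ceil(r_px)) + 2
    ylo, yhi = max(0, int(y0) - pad), min(height, int(y0) + pad + 1)
    yy = np.arange(ylo, yhi)[:, None]
    for x0 in positions:
        for cx in (x0, x0 + dx_px):
            xlo, xhi = max(0, int(cx) - pad), min(width, int(cx) + pad + 1)
            xx = np.arange(xlo, xhi)[None, :]
            dist = np.sqrt((yy - y0) ** 2 + (xx - cx) ** 2)
            disc = np.clip(r_px - dist + 0.5, 0.0, 1.0)  # anti-aliased disc
            patch = _BACKGROUND + (_FOREGROUND - _BACKGROUND) * disc
            img[ylo:yhi, xlo:xhi] = np.maximum(img[ylo:yhi, xlo:xhi], patch)
    img = gaussian_filter(img, sigma=1.0)
    img += rng.normal(0.0, spec.noise_level * (_FOREGROUND - _BACKGROUND), img.shape)

    image = JetImage(
        img, spec.pixel_size_um, jet_axis="horizontal", modality="double_exposure"
    )
    return image, dx_um


def gen_velocity_dataset(
    coeffs: ScalingCoefficients,
    geometries: Sequence[float] = (30.0, 60.0, 60.0, 90.0),
    q_ranges: dict | None = None,
    n: int = 100,
    noise: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Jet-velocity measurement table following the scaling law with noise.

    Emulates a measurement campaign over several gas-aperture diameters
    (defaults are the four measured GDVN geometries) with liquid and gas
    flows drawn uniformly from the measured envelope.  Velocities carry
    multiplicative Gaussian noise: v = v_model * (1 + eps).
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    q_ranges = q_ranges or {"q_liquid": (5.0, 100.0), "q_gas": (10.0, 40.0)}
    rng = np.random.default_rng(seed)
    d_gas = np.asarray(
        [getattr(g, "d_gas_um", g) for g in geometries], dtype=float
    )[np.arange(n) % len(geometries)]
    ql = rng.uniform(*q_ranges["q_liquid"], n)
    qg = rng.uniform(*q_ranges["q_gas"], n)
    v = coeffs.a + coeffs.b * np.sqrt(qg / d_gas**2) / ql**0.25
    v = v * (1.0 + rng.normal(0.0, noise, n)) if noise > 0 else v
    return pd.DataFrame(
        {"q_liquid_ul_min": ql, "q_gas_mg_min": qg, "d_gas_um": d_gas, "v_m_s": v}
    )


def gen_droplet_trace(
    mode_diameter_nm: float = 100.0,
    gsd: float = 1.5,
    n_bins: int = 64,
    seed: int = 0,
    noise: float = 0.02,
) -> tuple[SizeDistribution, dict]:
    """Lognormal number-weighted size trace plus analytic ground truth.

    ``mode_diameter_nm`` is the mode of the number-weighted distribution and
    ``gsd`` the geometric standard deviation.  The volume-weighted mode is
    then mode * exp(3 ln^2 gsd), returned in the ground-truth dict.
    """
    if gsd <= 1:
        raise ValueError("gsd must exceed 1")
    sigma = math.log(gsd)
    mu = math.log(mode_diameter_nm) + sigma**2  # number-mode convention
    volume_mode = mode_diameter_nm * math.exp(3.0 * sigma**2)

    lo = mode_diameter_nm / gsd**4
    hi = volume_mode * gsd**4
    d = np.geomspace(lo, hi, n_bins)
    pdf = np.exp(-((np.log(d) - mu) ** 2) / (2 * sigma**2)) / d
    rng = np.random.default_rng(seed)
    conc = pdf / pdf.max() * (1.0 + rng.normal(0.0, noise, n_bins))
    conc = np.clip(conc, 0.0, None)
    dist = SizeDistribution(d, conc)
    truth = {
        "number_mode_nm": mode_diameter_nm,
        "volume_mode_nm": volume_mode,
        "gsd": gsd,
        "bin_width_factor": float(d[1] / d[0]),
    }
    return dist, truth


@njit(cache=False, fastmath=True)
def _explicit_march(c, h, dt, diffusivity, threshold, max_steps):  # pragma: no cover
    m = c.shape[0]
    # precomputed update coefficients: dc_j = ap[j](c_{j+1}-c_j) - am[j](c_j-c_{j-1})
    k = dt * diffusivity / (h * h)
    ap = np.empty(m)
    am = np.empty(m)
    for j in range(1, m - 1):
        rho = j * h
        ap[j] = k * (1.0 + h / (2.0 * rho))
        am[j] = k * (1.0 - h / (2.0 * rho))
    nxt = np.empty_like(c)
    t = 0.0
    prev = c[0]
    for _ in range(max_steps):
        nxt[0] = c[0] + 4.0 * k * (c[1] - c[0])
        for j in range(1, m - 1):
            nxt[j] = c[j] + ap[j] * (c[j + 1] - c[j]) - am[j] * (c[j] - c[j - 1])
        nxt[m - 1] = c[m - 1] + 2.0 * k * (c[m - 2] - c[m - 1])
        c, nxt = nxt, c
        t += dt
        if c[0] >= threshold:
            frac = 0.0
            if c[0] > prev:
                frac = (c[0] - threshold) / (c[0] - prev)
            return t - dt * frac
        prev = c[0]
    return -1.0


def gen_mixing_reference(
    problem: MixingProblem,
    fine_nodes: int = 4000,
    dt_s: float | None = None,
    t_max_s: float | None = None,
) -> float:
    """Independent fine-grid reference mixing time (ms) for the mixing solver.

    Explicit-Euler marching of the dimensional radial diffusion equation on
    a node-centred grid (r = 0 ... R).  Deliberately discretised differently
    from the production solver (node- vs cell-centred, explicit vs implicit)
    so the two are independent routes to the same continuum problem.
    """
    if fine_nodes < 4000:
        raise ValueError("fine grid requires at least 4000 radial nodes")
    if problem.depletion != "none":
        raise ValueError("reference solver covers the no-depletion baseline only")
    radius_m = problem.channel_radius_um * 1e-6
    r_inner_m = focused_stream_radius(problem.frr, problem.channel_radius_um) * 1e-6
    rho_inner = r_inner_m / radius_m
    if problem.threshold_fraction >= 1.0 - rho_inner**2:
        raise ValueError("threshold unreachable")

    h = radius_m / (fine_nodes - 1)
    cfl_limit = 0.25 * h**2 / problem.diffusivity_m2_s
    if dt_s is None:
        dt_s = 0.2 * h**2 / problem.diffusivity_m2_s
    elif dt_s > cfl_limit:
        raise ValueError(f"CFL violation: dt must not exceed {cfl_limit:.3e} s")
    if t_max_s is None:
        t_max_s = 0.5 * radius_m**2 / problem.diffusivity_m2_s

    r = np.arange(fine_nodes) * h
    c = np.clip((r - r_inner_m) / h + 0.5, 0.0, 1.0)
    t_cross = _explicit_march(
        c, h, dt_s, problem.diffusivity_m2_s, problem.threshold_fraction,
        int(math.ceil(t_max_s / dt_s)),
    )
    if t_cross < 0:
        raise RuntimeError("no threshold crossing within the integration horizon")
    return t_cross * 1e3
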