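# Methods

This note records the models implemented in `jetkit`, their assumptions,
the numerical choices made where the design was open, and what the
synthetic-data generators do and do not emulate.

## Pulse-train timing

The machine modes are stored by their exact inter-pulse spacings (221.6,
443.3, 886.5, 1773.0 ns with 2700/1350/352/202 pulses per 10 Hz train).
The megahertz figures commonly attached to these modes (4.51, 2.26, 1.13,
0.564 MHz) are rounded labels: 1/886.5 ns = 1.128 MHz, not 1.13.  All rates
are therefore derived from the spacings, never from the labels; this is
the only convention under which the displacement/velocity arithmetic and
the printed train durations are simultaneously self-consistent.

Train duration is computed as `n_pulses × spacing`.  The alternative
`(n−1) × spacing` convention (time from first to last pulse) does not
reproduce the published 598/598/312/358 µs round-off for all four modes;
the chosen convention does.

Required jet velocity is v = Δx · f/k with integer pump divisor k ≥ 1 for
pump–probe schemes where only every k-th pulse is pumped.  Reporting
granularity follows the published tables: velocities to 0.1 m/s,
displacements to 1 µm, durations to 1 µs.

## GDVN jet velocity and diameter

The pressure drop across the focusing meniscus is approximated by
ΔP ≃ Q_g/D², and theory predicts v ≃ ΔP^½.  Measured jets show an
additional liquid-flow dependence captured by the empirical law

    v = a + b (Q_g/D²)^½ / Q_l^¼,    a = 8.35 m/s,  b = 1022,

whose unit contract is fixed (Q_g in mg/min, D in µm, Q_l in µl/min,
v in m/s).  There is no physical derivation of the Q_l^(−1/4) factor; the
constants are treated as empirical and valid only inside the measured
envelope, taken as Q_l ∈ [5, 100] µl/min, Q_g ∈ [10, 40] mg/min,
D ∈ [30, 145] µm.  Outside it the predictor warns (`ExtrapolationWarning`)
but never refuses — extrapolation is often exactly what a planning
calculation needs, flagged.  The constants hold for in-vacuum jetting; an
opt-in flag applies the roughly five-fold speed-up observed in
atmospheric-pressure chambers.

Jet diameter follows from volume conservation, d = [4Q_l/(πv)]^½.  In the
regime where the offset a is negligible, combining the two relations gives
d ∝ Q_l^(5/8)/(Q_g/D²)^(1/4); the test suite verifies the 5/8 exponent
numerically in the a → 0 limit.

Refitting (a, b) is ordinary least squares of v on x = (Q_g/D²)^½/Q_l^¼,
unweighted and on untransformed velocities.  An identifiability caveat
discovered while validating the fit: with multiplicative noise of 5% and
n = 100 rows spread over the measured envelope, the standard error of the
intercept a is 0.25–0.5 m/s — i.e. 3–6% of a itself — because a (8.35 m/s)
is small compared with typical jet velocities (15–150 m/s) and unweighted
OLS lets the noisy fast-jet rows dominate.  The scale factor b, by
contrast, is determined to well under 2%.  Recovering a reliably to a few
percent requires either a weighted fit or a measurement campaign
concentrated at the velocity extremes; with envelope-spanning data the
offset should be quoted with its standard error, which `ScalingLawFit`
reports.

HVE stream velocity is plug flow through the capillary bore,
v = Q/(π ID²/4); with 0.05–2.0 µl/min through a 100 µm ID this spans
~0.1–4.2 mm/s, which is why high-viscosity extrusion is compatible only
with single-pulse 10 Hz trains.

## Image velocimetry

Only straight jets along a declared image axis are supported.  Both
estimators first locate the transverse band occupied by the jet (rows
whose mean exceeds the midpoint of the row-mean range) and project the
image onto the jet axis over that band.

**Gap trains.**  Axial positions are classified as gap where the profile
falls below 50% of the median *on-jet* intensity; the on-jet median is
taken over columns pre-classified as jet by a min/max split, because with
slow jets the gaps can occupy most of the axis and a whole-profile median
would sit inside a gap.  Each interior contiguous gap segment contributes
one midpoint: the centroid of the intensity deficit, which is sub-pixel
accurate for symmetric gaps.  Segments touching the image border are
discarded as truncated.  Velocity is the mean consecutive spacing times
the intra-train rate.

**Dual-pulse droplet imaging.**  The mean-subtracted axial profile is
autocorrelated; when every droplet appears twice at offset Δx, the
autocorrelation has a coherent peak at Δx carrying about half the zero-lag
power.  The estimator takes the first local maximum beyond the central
lobe (past the first local minimum) that exceeds both a 4σ tail-noise
floor and an absolute 0.2 in normalised units, and refines it with a
three-point parabolic fit.  Isolated, unpaired droplets produce no such
peak and raise an error.

Accuracy characterisation (Monte-Carlo against generator ground truth):
the gap-train pipeline recovers velocities to ≲0.1%; the dual-pulse
pipeline is limited by coincidence contamination — chance droplet spacings
falling near the true offset — and reaches ~1.5% worst-case when the
offset is ~20 px and ≥20–30 droplet pairs are imaged.  With few pairs
(~10) the first-peak rule occasionally locks onto a chance-coincidence
ghost; plan dual-pulse measurements with dense droplet trains, or
average repeated frames.

## Diffusive mixing

The concentric-cones mixer focuses the sample into a central stream of
radius r_in = R (q_sample/q_total)^½ — a plug-flow area partition,
justified because the design centres the sample in the parabolic profile
precisely to minimise velocity mismatch (Taylor dispersion).  Parabolic
corrections are out of scope.  Dilution is (q_sheath+q_sample)/q_sample.

Mixing time solves the radial diffusion equation
∂c/∂t = D (1/r) ∂/∂r (r ∂c/∂r) on 0 ≤ r ≤ R with zero-flux walls and the
step initial condition c = 0 (r < r_in), c = c₀ (r ≥ r_in).  The mixing
criterion is the earliest time the *centreline* — the most slowly mixed
point — reaches a threshold fraction (default 12.5%) of c₀.  Whether such
a threshold should be read at the centreline or as a cross-section average
is a modelling choice; the centreline is the strictest and is what this
package implements.  The threshold is checked against the equilibrium
centreline fraction 1 − (r_in/R)² and rejected as unreachable beyond it.

Numerics: the problem is nondimensionalised (τ = tD/R²), so the R²/D
self-similarity — doubling D exactly halves t_mix — holds to machine
precision by construction.  Space is discretised by a conservative
cell-centred finite-volume scheme (400 cells by default; cross-sectional
reactant mass is conserved to ~1e-13 relative).  Time stepping is
Crank–Nicolson preceded by 50 backward-Euler quarter-steps that damp the
discontinuous initial interface (plain Crank–Nicolson rings on step data).
The crossing time is interpolated linearly within the bracketing step.  By
default each solve is repeated on a doubled grid and a warning raised if
the answer moves by more than 0.5%.

Verification is three-way: the production solver, an intentionally
different reference (node-centred, dimensional, explicit Euler at
CFL-limited steps on ≥4000 nodes, numba-compiled), and a Bessel-series
closed form (J₀ eigenfunction expansion with J₁ roots).  Across a 3×3×3
grid of focusing ratio × diffusivity × threshold the production solver
agrees with the explicit reference to better than 0.05% and with the
series to ~1e-4 relative.

Defaults reflect the lysozyme/glucose design point: D = 6.0×10⁻¹⁰ m²/s
(the glucose diffusion coefficient; one source prints "6.0 × 10 m² s⁻¹",
an evident exponent typo), 30 mM reactant against 3.5 mM protein sites,
12.5% threshold.  An optional first-order sink in the sample core stands
in for reactant consumption by protein; it is off by default and carries
no quantitative calibration.  For the 200 µm channel at a 10:1 flow-rate
ratio this yields t_mix ≈ 182 ms; at ~108 µl/min total flow a 500 ms
probed time point corresponds to ~28.6 mm of channel, consistent with the
28.8 mm device built for that regime (the exact flow used with that device
is not recorded, so this is a consistency check, not a reproduction).

Channel length for a delay is L = t·Q/(πR²) (plug flow); the residence
time of a mixer-to-nozzle capillary extension is its volume over the flow.

## Electrospray droplet sizing

Spraying a solution with involatile volume fraction c and measuring the
dried residue D_res fixes the initial droplet diameter D = D_res/c^⅓
(e.g. 5% sucrose: a 100 nm residue implies a 271 nm droplet).  Because a
sample particle's chance of landing in a droplet scales with droplet
volume, reported sizes use the mode of the D³-weighted distribution,
computed per-bin without smoothing.

Measurements at different conductivities collapse in the dimensionless
coordinates Q/Q_σ = QKρ/(σε₀) and D/D_σ = D[K²ρ/(σε₀²)]^⅓ (ε₀ at the
CODATA value; water defaults ρ = 1000 kg/m³, σ = 0.072 N/m).  Below
Q/Q_σ = 1000 the cone-jet scaling D ∝ Q^⅓ applies; the boundary point is
assigned to the steeper super-threshold regime, which the module
classifies but does not fit (its exponent is not established).

## Acquisition planning and the device catalog

Acquisition time is t = N_indexed/(hit · index · pulses/s); human-readable
output rounds to the nearest minute below 10 min and to one significant
figure above (so 284 s → "5 min", 1705 s → "30 min").  Data quality scales
as √N patterns.  Hit rate is an input, not modelled.

The catalog ships all 21 catalogued designs (GDVN, micromixer,
mixing-GDVN, DFFN, HVE, mixing-HVE, CCT) with geometry strings, minimum
(and where given, maximum) liquid flows and rated pulse modes.  Rated-mode
labels ("≤1.1 MHz" etc.) are resolved to the exact canonical intra-train
rates they denote, so the 1.13 MHz machine mode is compatible with a
"≤1.1 MHz" device, as intended by the rating.  HVE-class devices are
compatible only with single-pulse trains.  Upper flow bounds are stored
but not enforced in selection (treated as informational).  Micromixer
rows carry no rate limit of their own — the attached nozzle limits them.
The DFFN's ethanol sheath requirement is carried as a flag plus its own
minimum flow.  The 2×10⁻⁴ mbar chamber-pressure limit for detector
operation is exposed as an advisory constant only; no vacuum model is
implemented.

## Synthetic data generators

All generators take a mandatory integer seed and are bit-identical under
regeneration.  Images emulate the in-chamber side-view microscope
(1075×310 px, 0.65 µm/px): a bright jet band or droplet discs rendered
with anti-aliased (area-coverage) edges, a 1 px Gaussian blur, then
additive Gaussian noise of σ = noise_level × dynamic range.  Poisson shot
noise, optical point-spread detail, jet curvature and the shock-wave
physics of the real explosions are deliberately not modelled — passing
recovery tests therefore demonstrates the correctness of the estimators'
geometry and sub-pixel interpolation under calibrated noise, not their
robustness to real-beamline artefacts (illumination gradients, debris,
satellite droplets).

Gap images place gaps at exactly v/f spacing with a seeded random phase
and return the true midpoints of the fully interior gaps.  Double-exposure
images place droplet pairs at uniform random axial positions with a
minimum separation of 3 droplet diameters and return the true offset
v·Δt; an offset exceeding the separation floor triggers a pairing-
ambiguity warning.  Velocity tables draw flows uniformly from the measured
envelope across the four measured gas-aperture diameters (30, 60, 60,
90 µm) and apply multiplicative Gaussian noise.  Size traces are lognormal
in number weight with the number mode and GSD as parameters; the
volume-weighted mode has the closed form mode × exp(3 ln² GSD), returned
as ground truth.  The mixing reference solver is described above.

## Known limitations

- The scaling-law constants are empirical and extrapolation beyond the
  measured envelope is flagged, not validated.
- No compressible-gas model links helium supply pressure to mass flow;
  printed (pressure, flow) pairs are treated as given.
- The mixing solver assumes plug flow and pure diffusion; Kenics-type
  helical mixers are catalogued but their flow-splitting physics is not
  modelled.
- Dual-pulse velocimetry assumes a dense droplet train; sparse trains can
  defeat the first-peak rule (see the accuracy characterisation above).
- Diffraction-data quantities (hit finding, indexing, R-factors) are
  outside scope; the planner treats hit and indexing rates as inputs.
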