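# jetkit

Planning and analysis toolkit for liquid sample delivery at megahertz
X-ray free-electron lasers (XFELs).

Serial femtosecond crystallography (SFX) and single-particle imaging
consume a stream of fresh sample: every X-ray pulse destroys what it hits,
so crystals or particles must be replenished between pulses arriving as
little as ~222 ns apart.  `jetkit` collects the quantitative design rules
that connect the machine's pulse structure to the injection hardware —
gas-dynamic virtual nozzles (GDVN), mix-and-inject micromixers,
high-viscosity extruders (HVE) and electrospray emitters — so that an
experiment can be planned on paper before sample is committed.

## What it computes

**Pulse timing → jet speed** (`jetkit.timing`).  X-rays arrive in 10 Hz
trains of up to 2700 pulses with intra-train rates up to 4.5 MHz.  A jet
must displace each probed volume by Δx between pulses, requiring
v = Δx · f_pulse.  The four canonical machine modes are built in.

**GDVN jet scaling** (`jetkit.jet_model`).  In-vacuum jet velocities follow
the empirical law

    v_jet = a + b · (Q_g / D²)^½ / Q_l^¼ ,   a = 8.35, b = 1022

with the helium mass flow Q_g in mg min⁻¹, gas aperture D in µm and liquid
flow Q_l in µl min⁻¹ giving v in m s⁻¹.  Volume conservation then fixes the
jet diameter, d_jet = [4 Q_l/(π v)]^½.  The module predicts, warns on
extrapolation outside the measured envelope, and refits (a, b) from
measurement tables.  Plug-flow HVE stream velocities are included.

**Image velocimetry** (`jetkit.velocimetry`).  Two micrograph-based
measurements: gap-train (X-ray-induced gaps in the jet, v = Δx · f) and
dual-pulse droplet imaging (v = Δx/Δt), with sub-pixel gap-centroid and
autocorrelation-peak estimators.  Pre-measured scalars can be replayed
without images.

**Mix-and-inject design** (`jetkit.mixing`).  Dilution from flow-rate
ratios, hydrodynamically focused stream radius, diffusive mixing time from
a conservative radial-diffusion solver (centreline threshold criterion),
and channel length / capillary residence-time bookkeeping.

**Electrospray sizing** (`jetkit.electrospray`).  Residue-to-droplet
calibration D = D_res/c^⅓, the dimensionless coordinates
Q/Q_σ = QKρ/(σε₀) and D/D_σ = D[K²ρ/(σε₀²)]^⅓, cone-jet regime
classification (Q/Q_σ < 1000) and volume-weighted distribution modes.

**Acquisition planning** (`jetkit.planner`).  t = N_indexed/(hit · index ·
pulses/s), √N data-quality scaling, and selection from the bundled
device catalog by pulse-mode and flow compatibility.

**Synthetic data** (`jetkit.synthetic`).  Seeded generators with exact
ground truth for every input class: gap-train and double-exposure
micrographs, scaling-law measurement tables, lognormal size traces, and an
independent fine-grid reference solver for the mixing module.

## Worked example

```python
from jetkit import timing as T, jet_model as J, planner as P

mode = T.canonical_mode("1.13 MHz")
v_need = T.required_jet_velocity(T.ReplenishmentRequirement(44.0), mode)
v_pred = J.predict_jet_velocity(J.FlowConditions(10.0, 25.0), J.NozzleGeometry(75, 60, 75))
print(f"required {v_need:.1f} m/s, predicted {v_pred:.1f} m/s")
print(f"jet diameter {J.jet_diameter(10.0, v_pred):.1f} um")
t = P.acquisition_time(P.AcquisitionParams(5000, 0.01, 0.5, 3520))
print(f"5000 indexed patterns in {P.format_acquisition_time(t)}")
```

prints

```
required 49.6 m/s, predicted 56.2 m/s
jet diameter 1.9 um
5000 indexed patterns in 5 min
```

i.e. a 75–60–75 µm nozzle at 10 µl min⁻¹ liquid and 25 mg min⁻¹ helium
produces a ~2 µm jet fast enough (56.2 ≥ 49.6 m s⁻¹) for 1.13 MHz
operation, and a minimal SFX data set takes about five minutes of beam
time.  The `examples/` directory holds one narrative script per module;
each builds a small input, runs the method and explains the numbers it
prints.

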