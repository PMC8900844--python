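"""Predict gas-focused jet velocity and diameter, and refit the scaling law.

The empirical law v = a + b (Q_g/D^2)^(1/2) / Q_l^(1/4) predicts in-vacuum
GDVN jet velocities from the helium mass flow Q_g (mg/min), the gas aperture
D (um) and the liquid flow Q_l (ul/min).
"""

from jetkit import jet_model as J
from jetkit.synthetic import gen_velocity_dataset

# Operating point of a mixing-GDVN: 34 mg/min He through a 90 um aperture,
# 77 ul/min total liquid after an 11-fold dilution.
flow = J.FlowConditions(q_liquid_ul_min=77.0, q_gas_mg_min=34.0)
nozzle = J.NozzleGeometry(d_liquid_um=100.0, d_gas_um=90.0, h_liquid_gas_um=100.0)
pred = J.predict(flow, nozzle)
print(f"predicted jet velocity: {pred.velocity_m_s:.1f} m/s")
print(f"implied jet diameter:   {pred.diameter_um:.1f} um")
print(f"pressure-drop proxy:    {pred.pressure_drop_proxy:.2e} mg/min/um^2")

# A thin fast jet: 10 ul/min water, 25 mg/min He, 60 um aperture.
thin = J.predict(J.FlowConditions(10.0, 25.0), J.NozzleGeometry(75, 60, 75))
print(f"\nthin-jet point: {thin.velocity_m_s:.1f} m/s, {thin.diameter_um:.1f} um")

# Refit (a, b) from a synthetic measurement campaign with 5% noise:
table = gen_velocity_dataset(J.ScalingCoefficients(), n=100, noise=0.05, seed=11)
fit = J.fit_scaling_law(table)
print(
    f"\nrefit from {fit.n} noisy rows: a = {fit.coefficients.a:.2f} "
    f"(+/- {fit.stderr_a:.2f}), b = {fit.coefficients.b:.0f} (+/- {fit.stderr_b:.0f}),"
    f" rmse {fit.rmse:.2f} m/s"
)
print("the scale b is tightly determined; the small offset a much less so")

# High-viscosity extrusion streams are five orders of magnitude slower:
print(f"\nHVE: 2.0 ul/min in 100 um ID -> {J.hve_stream_velocity(2.0, 100.0):.1f} mm/s")
print(f"HVE: 0.3 ul/min in  75 um ID -> {J.hve_stream_velocity(0.3, 75.0):.1f} mm/s")
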