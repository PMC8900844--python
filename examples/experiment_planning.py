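"""Plan a serial-crystallography shift: acquisition time and device choice."""

from jetkit import jet_model as J, planner as P, timing as T

# How long to collect 5000 indexed patterns at 1% hit rate, 50% indexing,
# 3520 pulses per second (the 1.13 MHz mode)?
params = P.AcquisitionParams(
    n_indexed_target=5000, hit_rate=0.01, indexing_rate=0.5, pulses_per_second=3520
)
t = P.acquisition_time(params)
print(f"minimal data set: {t:.0f} s ({P.format_acquisition_time(t)})")

t30 = P.acquisition_time(P.AcquisitionParams(30000, 0.01, 0.5, 3520))
print(f"redundant data set: {t30:.0f} s ({P.format_acquisition_time(t30)})")
print(f"quality gain from 6x patterns: x{P.relative_quality(30000, 5000):.2f}")

# Which injection devices support 1.13 MHz operation at 10 ul/min sample?
mode = T.canonical_mode("1.13 MHz")
catalog = P.load_catalog()
compatible = P.select_devices(catalog, mode, q_liquid_ul_min=10.0)
print(f"\ndevices compatible with {mode.label} at 10 ul/min:")
for rec in compatible:
    print(f"  {rec.design_name:<9} {rec.device_type:<12} ({rec.geometry} um)")

# Is a predicted jet fast enough for the mode's replenishment requirement?
v_pred = J.predict_jet_velocity(J.FlowConditions(10.0, 25.0), J.NozzleGeometry(75, 60, 75))
v_need = T.required_jet_velocity(T.ReplenishmentRequirement(44.0), mode)
check = P.check_replenishment(v_pred, v_need)
print(
    f"\npredicted {v_pred:.1f} m/s vs required {v_need:.1f} m/s -> "
    f"{'OK' if check.ok else 'too slow'} (margin {check.margin_m_s:+.1f} m/s)"
)
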