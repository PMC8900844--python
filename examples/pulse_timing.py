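"""How fast must a liquid jet run for each EuXFEL pulse mode?

Walks the four canonical machine modes, prints their train structure, and
converts a sample-displacement requirement into a minimum jet velocity.
"""

from jetkit import timing as T

print(f"{'mode':>10} {'spacing ns':>11} {'pulses':>7} {'train us':>9} {'pulses/s':>9}")
for label, mode in T.CANONICAL_MODES.items():
    print(
        f"{label:>10} {mode.pulse_spacing_ns:>11.1f} {mode.pulses_per_train:>7d}"
        f" {T.train_duration(mode):>9.0f} {T.pulses_per_second(mode):>9.0f}"
    )

# A jet must move each probed volume out of the beam before the next pulse.
# At 1.13 MHz, a 44 um displacement between pulses requires:
mode = T.canonical_mode("1.13 MHz")
req = T.ReplenishmentRequirement(displacement_um=44.0)
v = T.required_jet_velocity(req, mode)
print(f"\n44 um displacement at 1.13 MHz -> jet velocity {v:.1f} m/s")

# Halving the repetition rate doubles the displacement of the same jet:
for label in ("1.13 MHz", "0.564 MHz"):
    dx = T.displacement_between_pulses(v, T.canonical_mode(label))
    print(f"  same jet at {label}: {dx:.0f} um between pulses")

# Pump-probe with the pump laser on every second pulse relaxes the requirement:
v2 = T.required_jet_velocity(T.ReplenishmentRequirement(44.0, pump_divisor=2), mode)
print(f"pumping every 2nd pulse -> only {v2:.1f} m/s needed")
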