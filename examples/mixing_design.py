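"""Design a mix-and-inject experiment: dilution, mixing time, channel length.

Crystals in the central stream are hydrodynamically focused by the reactant
sheath; the reactant then diffuses inward.  The mixing time is when the
centreline reaches 12.5% of the sheath concentration.
"""

from jetkit import mixing as M

# 10:1 water:sample flow-rate ratio in the 200 um mixing channel
frr = M.FlowRateRatio.from_string("10:1", q_sample_ul_min=9.8)
geometry = M.MIXER_GEOMETRIES["MVED_Z"]
print(f"flow-rate ratio 10:1 -> {M.dilution_factor(frr):.0f}-fold dilution")
r_inner = M.focused_stream_radius(frr, geometry.channel_radius_um)
print(f"focused sample stream radius: {r_inner:.1f} um in R = {geometry.channel_radius_um:.0f} um")

problem = M.MixingProblem(frr=frr, channel_radius_um=geometry.channel_radius_um)
result = M.mixing_time(problem)
print(
    f"mixing time to 12.5% centreline (glucose, D = 6e-10 m^2/s): "
    f"{result.t_mix_ms:.0f} ms"
)
print(f"channel length needed at {frr.q_total_ul_min:.1f} ul/min: {result.l_required_mm:.1f} mm")

# Longer delays via a capillary extension between mixer and nozzle:
t_ext = M.delay_for_capillary_extension(28.0, 108.0, 200.0)
print(f"\n28 mm x 200 um ID extension at 108 ul/min adds {t_ext:.0f} ms delay")
length = M.channel_length_for_delay(500.0, 108.0, 100.0)
print(f"a 500 ms time point at 108 ul/min needs {length:.1f} mm of 200 um channel")
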