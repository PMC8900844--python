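"""Unit conversion constants shared across modules (SI internally)."""

#: microlitres per minute -> m^3/s
UL_MIN_TO_M3_S = 1e-9 / 60.0
#: nanolitres per minute -> m^3/s
NL_MIN_TO_M3_S = 1e-12 / 60.0
#: CODATA vacuum permittivity, F/m
EPSILON_0 = 8.8541878128e-12
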