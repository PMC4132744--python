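"""Physical constants in the package's nm/nN unit system."""

# Boltzmann constant: 1.380649e-23 J/K expressed in nN*nm per kelvin
# (1 J = 1e9 nN * 1e9 nm = 1e18 nN*nm).
BOLTZMANN_NN_NM_PER_K = 1.380649e-5

ROOM_TEMPERATURE_K = 298.0
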