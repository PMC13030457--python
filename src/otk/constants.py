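"""Physical constants (SI units)."""

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN = 1.380649e-23
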