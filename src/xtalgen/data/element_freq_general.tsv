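# Default element frequencies for general-position (non-hydrogen) atoms.
# Approximation constrained so that C+N+O = 89% of non-hydrogen atoms,
# with the remainder spread over common hetero elements and first-row
# transition metals. Replaceable via configuration.
# element	frequency
C	0.620
N	0.120
O	0.150
S	0.030
Cl	0.025
F	0.020
P	0.015
Br	0.008
Si	0.004
Fe	0.002
Cu	0.002
Zn	0.001
Ni	0.001
Mn	0.001
Co	0.0005
Ti	0.0005
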