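# Default element frequencies for special-position (inversion-center) atoms.
# Approximation constrained so that C+N+O = 49%, with transition metals
# upweighted (inversion-symmetric coordination complexes). Replaceable via
# configuration.
# element	frequency
C	0.250
N	0.100
O	0.140
Fe	0.080
Cu	0.080
Ni	0.060
Co	0.050
Mn	0.050
Zn	0.050
Cr	0.020
Ti	0.020
V	0.010
S	0.030
Cl	0.030
Br	0.015
P	0.010
F	0.005
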