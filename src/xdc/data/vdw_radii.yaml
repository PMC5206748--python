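# Element-wise van der Waals radii in Angstrom (Bondi-style set).
# Overlap volumes and clash calls depend on this table; swap it via
# the --radii option or the `radii=` keyword to make that dependence explicit.
C: 1.70
N: 1.55
O: 1.52
S: 1.80
H: 1.20
P: 1.80
SE: 1.90
F: 1.47
CL: 1.75
BR: 1.85
I: 1.98
CA: 2.31
ZN: 1.39
MG: 1.73
NA: 2.27
K: 2.75
FE: 1.94
DEFAULT: 1.70
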