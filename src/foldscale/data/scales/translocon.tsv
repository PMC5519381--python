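# Translocon ("biological") hydrophobicity scale: apparent free energy of
# membrane insertion dG_app (kcal/mol) at the most favorable helix position.
# Transcribed from Hessa et al., Nature 433:377 (2005).
residue	value
A	0.11
R	2.58
N	2.05
D	3.49
C	-0.13
Q	2.36
E	2.68
G	0.74
H	2.06
I	-0.60
L	-0.55
K	2.71
M	-0.10
F	-0.32
P	2.23
S	0.84
T	0.52
W	0.30
Y	0.68
V	-0.31
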