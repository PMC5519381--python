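# Side-chain accessible-surface-area table (A^2).
# delta_nonpolar: apolar (C/S) side-chain ASA change upon folding;
# delta_total: total side-chain ASA (Gly-X-Gly standard state);
# avg_buried: mean side-chain area buried upon folding.
# Approximate transcription of standard literature tables
# (Miller, Janin, Lesk & Chothia, J Mol Biol 196:641, 1987;
# Rose, Geselowitz, Lesser, Lee & Zehfus, Science 229:834, 1985).
# Verify against the originals before quantitative use.
residue	delta_nonpolar	delta_total	avg_buried
A	67	67	62
R	89	196	99
N	44	113	60
D	48	106	58
C	98	104	91
Q	53	144	73
E	61	138	67
G	25	25	40
H	102	151	95
I	140	140	114
L	137	137	112
K	119	167	78
M	117	160	122
F	175	175	133
P	105	105	65
S	44	80	50
T	74	102	65
W	190	217	146
Y	144	187	117
V	117	117	95
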