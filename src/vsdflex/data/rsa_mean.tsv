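# Mean relative solvent accessibility (RSA) per residue type: typical
# fraction of the side chain's maximal accessible surface that is
# solvent-exposed in folded globular/membrane-adjacent proteins.
# Charged and polar residues are predominantly exposed, aliphatic and
# aromatic residues predominantly buried.  Fractions in [0, 1].
residue	value
A	0.48
R	0.56
N	0.62
D	0.63
C	0.32
Q	0.62
E	0.66
G	0.51
H	0.49
I	0.28
L	0.28
K	0.71
M	0.33
F	0.24
P	0.58
S	0.55
T	0.49
W	0.25
Y	0.32
V	0.30
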