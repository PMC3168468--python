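# Residue hydrophobicity indexes in kcal/mol, from thermodynamic
# transfer-free-energy measurements (Nozaki-Tanford-derived compilation,
# Jones 1975).  Replace this file, or pass --scale, to use another scale;
# every report records the provenance label of the scale actually used.
# provenance: transfer-free-energy (Jones 1975)
residue_name	h_kcal_per_mol
ALA	0.87
ARG	0.85
ASN	0.09
ASP	0.66
CYS	1.52
GLN	0.00
GLU	0.67
GLY	0.10
HIS	0.87
ILE	3.15
LEU	2.17
LYS	1.64
MET	1.67
PHE	2.87
PRO	2.77
SER	0.07
THR	0.07
TRP	3.77
TYR	2.67
VAL	1.87
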