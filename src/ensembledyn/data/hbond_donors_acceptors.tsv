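# Donor/acceptor atom table for geometric hydrogen-bond detection.
# role: donor rows name the heavy atom and the hydrogen(s) attached to it
# (comma-separated); acceptor rows name the accepting heavy atom.
# residue_name "*" applies to every residue (backbone chemistry).
# The table follows standard amino-acid chemistry and is editable; pass an
# alternative file to use different naming conventions or protonation states.
residue_name	role	heavy_atom	hydrogens
*	donor	N	H
*	acceptor	O
*	acceptor	OXT
SER	donor	OG	HG
SER	acceptor	OG
THR	donor	OG1	HG1
THR	acceptor	OG1
TYR	donor	OH	HH
TYR	acceptor	OH
CYS	donor	SG	HG
ASN	donor	ND2	HD21,HD22
ASN	acceptor	OD1
GLN	donor	NE2	HE21,HE22
GLN	acceptor	OE1
ASP	acceptor	OD1
ASP	acceptor	OD2
GLU	acceptor	OE1
GLU	acceptor	OE2
HIS	donor	ND1	HD1
HIS	donor	NE2	HE2
HIS	acceptor	ND1
HIS	acceptor	NE2
LYS	donor	NZ	HZ1,HZ2,HZ3
ARG	donor	NE	HE
ARG	donor	NH1	HH11,HH12
ARG	donor	NH2	HH21,HH22
TRP	donor	NE1	HE1
MET	acceptor	SD
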