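# Hydrogen-bond donor/acceptor typing, editable without code changes.
# kind: protein | ligand; role: donor | acceptor | both
# residue_name "*" matches the backbone atoms of any amino acid.
# Ligands: PEA beta-phenylethylamine, TYM tyramine, PUT putrescine,
# CAD cadaverine, ABU gamma-aminobutyric acid.
residue_name	atom_name	kind	role
*	N	protein	donor
*	O	protein	acceptor
ASP	OD1	protein	acceptor
ASP	OD2	protein	acceptor
GLU	OE1	protein	acceptor
GLU	OE2	protein	acceptor
SER	OG	protein	both
THR	OG1	protein	both
ASN	ND2	protein	donor
ASN	OD1	protein	acceptor
GLN	NE2	protein	donor
GLN	OE1	protein	acceptor
TYR	OH	protein	both
TRP	NE1	protein	donor
LYS	NZ	protein	donor
ARG	NE	protein	donor
ARG	NH1	protein	donor
ARG	NH2	protein	donor
HIS	ND1	protein	both
HIS	NE2	protein	both
PEA	N1	ligand	donor
TYM	N1	ligand	donor
TYM	O1	ligand	both
PUT	N1	ligand	donor
PUT	N2	ligand	donor
CAD	N1	ligand	donor
CAD	N2	ligand	donor
ABU	N1	ligand	donor
ABU	O1	ligand	acceptor
ABU	O2	ligand	acceptor
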