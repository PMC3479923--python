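# Side-chain pseudoatom mapping for the reduced protein model.
# One C-alpha bead per residue plus one side-chain bead (SC1) for small
# residues or two (SC1 + SC2, roughly a stem/tip split) for the large
# residues Arg, Lys, Glu, Gln, Met, Trp, Tyr, Phe and His.  Gly carries no
# side-chain bead.  Each bead is placed at the geometric centre of the heavy
# atoms listed (comma separated, PDB atom names).
#
# resname	bead	atoms
ALA	SC1	CB
SER	SC1	CB,OG
CYS	SC1	CB,SG
THR	SC1	CB,OG1,CG2
VAL	SC1	CB,CG1,CG2
LEU	SC1	CB,CG,CD1,CD2
ILE	SC1	CB,CG1,CG2,CD1
PRO	SC1	CB,CG,CD
ASP	SC1	CB,CG,OD1,OD2
ASN	SC1	CB,CG,OD1,ND2
HIS	SC1	CB,CG
HIS	SC2	ND1,CD2,CE1,NE2
PHE	SC1	CB,CG
PHE	SC2	CD1,CD2,CE1,CE2,CZ
TYR	SC1	CB,CG
TYR	SC2	CD1,CD2,CE1,CE2,CZ,OH
TRP	SC1	CB,CG,CD1
TRP	SC2	CD2,NE1,CE2,CE3,CZ2,CZ3,CH2
MET	SC1	CB,CG
MET	SC2	SD,CE
GLU	SC1	CB,CG
GLU	SC2	CD,OE1,OE2
GLN	SC1	CB,CG
GLN	SC2	CD,OE1,NE2
LYS	SC1	CB,CG,CD
LYS	SC2	CE,NZ
ARG	SC1	CB,CG,CD
ARG	SC2	NE,CZ,NH1,NH2
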