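# Canonical helix boundaries of the vertebrate globin fold, used only to
# attach helix-position labels (e.g. G3 = third residue of helix G) to
# rigidity-profile output.  Residue numbers follow the standard mature-chain
# numbering of haemoglobin alpha (141 aa) and beta (146 aa) subunits.
# chain_kind	helix	start	end
alpha	A	3	18
alpha	B	20	35
alpha	C	36	42
alpha	E	52	71
alpha	F	80	88
alpha	G	94	112
alpha	H	118	138
beta	A	5	18
beta	B	19	34
beta	C	36	41
beta	D	50	56
beta	E	57	76
beta	F	85	93
beta	G	99	117
beta	H	123	144
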