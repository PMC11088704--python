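# Random-coil chemical shift reference table (ppm).
# Records:
#   rc <residue 1-letter> <nucleus> <ppm>    random-coil shift
#   ref <helix|strand> <nucleus> <ppm>       average full-helix / full-strand
#                                            secondary shift (signed)
#   corr <prepro> <nucleus> <ppm>            additive correction to the
#                                            random-coil value of a residue
#                                            followed by proline
# Random-coil values follow the classical peptide reference compilations
# (Wishart-style GGXGG scales, pH ~5, 25 C); full-helix/full-strand averages
# are the consensus secondary-shift magnitudes used by propensity methods.
# Glycine has no CB; proline has no amide H. Values are a pinned reference:
# users may supply their own table in the same format.
rc	A	CA	52.5
rc	A	CB	19.1
rc	A	H	8.24
rc	R	CA	56.0
rc	R	CB	30.9
rc	R	H	8.23
rc	N	CA	53.1
rc	N	CB	38.9
rc	N	H	8.40
rc	D	CA	54.2
rc	D	CB	41.1
rc	D	H	8.34
rc	C	CA	58.2
rc	C	CB	28.0
rc	C	H	8.32
rc	Q	CA	55.7
rc	Q	CB	29.4
rc	Q	H	8.32
rc	E	CA	56.6
rc	E	CB	29.9
rc	E	H	8.42
rc	G	CA	45.1
rc	G	H	8.33
rc	H	CA	55.0
rc	H	CB	29.0
rc	H	H	8.42
rc	I	CA	61.1
rc	I	CB	38.8
rc	I	H	8.00
rc	L	CA	55.1
rc	L	CB	42.4
rc	L	H	8.16
rc	K	CA	56.2
rc	K	CB	33.1
rc	K	H	8.29
rc	M	CA	55.4
rc	M	CB	32.9
rc	M	H	8.28
rc	F	CA	57.7
rc	F	CB	39.6
rc	F	H	8.30
rc	P	CA	63.3
rc	P	CB	32.1
rc	S	CA	58.3
rc	S	CB	63.8
rc	S	H	8.31
rc	T	CA	61.8
rc	T	CB	69.8
rc	T	H	8.15
rc	W	CA	57.5
rc	W	CB	29.6
rc	W	H	8.25
rc	Y	CA	57.9
rc	Y	CB	38.8
rc	Y	H	8.12
rc	V	CA	62.2
rc	V	CB	32.9
rc	V	H	8.03
ref	helix	CA	3.1
ref	helix	CB	-0.5
ref	helix	H	-0.30
ref	strand	CA	-1.5
ref	strand	CB	2.2
ref	strand	H	0.35
corr	prepro	CA	-1.9
corr	prepro	CB	0.1
corr	prepro	H	0.05
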