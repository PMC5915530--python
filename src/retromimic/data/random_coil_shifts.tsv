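# Random-coil chemical shifts (ppm) for the 20 canonical amino acids.
# Nuclei: HA (1H-alpha), CA (13C-alpha), CB (13C-beta), HN (amide 1H).
# Values follow the standard peptide random-coil compilations measured on
# short unstructured model peptides in water (Wishart and co-workers,
# J. Biomol. NMR 1995, 5, 67-81; DSS-referenced). Glycine has no CB; proline
# has no amide HN. D-residues use the same values as their L-counterparts:
# chemical shifts are chirality-insensitive in an achiral solvent.
# This file is user-replaceable; CSD outputs record which table was used.
residue_code	nucleus	shift_ppm
A	HA	4.32
A	CA	52.5
A	CB	19.1
A	HN	8.24
R	HA	4.34
R	CA	56.0
R	CB	30.9
R	HN	8.23
N	HA	4.74
N	CA	53.1
N	CB	38.9
N	HN	8.40
D	HA	4.64
D	CA	54.2
D	CB	41.1
D	HN	8.34
C	HA	4.71
C	CA	58.2
C	CB	28.0
C	HN	8.32
Q	HA	4.34
Q	CA	55.7
Q	CB	29.4
Q	HN	8.32
E	HA	4.35
E	CA	56.6
E	CB	29.9
E	HN	8.42
G	HA	3.96
G	CA	45.1
G	HN	8.33
H	HA	4.73
H	CA	55.0
H	CB	29.0
H	HN	8.42
I	HA	4.17
I	CA	61.1
I	CB	38.8
I	HN	8.00
L	HA	4.34
L	CA	55.1
L	CB	42.4
L	HN	8.16
K	HA	4.32
K	CA	56.2
K	CB	33.1
K	HN	8.29
M	HA	4.48
M	CA	55.4
M	CB	32.9
M	HN	8.28
F	HA	4.62
F	CA	57.7
F	CB	39.6
F	HN	8.30
P	HA	4.42
P	CA	63.3
P	CB	32.1
S	HA	4.47
S	CA	58.3
S	CB	63.8
S	HN	8.31
T	HA	4.35
T	CA	61.8
T	CB	69.8
T	HN	8.15
W	HA	4.66
W	CA	57.5
W	CB	29.6
W	HN	8.25
Y	HA	4.55
Y	CA	57.9
Y	CB	38.8
Y	HN	8.12
V	HA	4.12
V	CA	62.2
V	CB	32.9
V	HN	8.03
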