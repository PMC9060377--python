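# Per-residue scalar properties used to build variant feature vectors.
# Columns are tab-separated; one row per canonical amino acid (one-letter code).
#
# hydrophobicity   octanol-water side-chain transfer scale (Fauchere & Pliska 1983);
#                  sign convention: more positive = more hydrophobic.  Replaceable by
#                  any membrane-transfer scale via --aa-table.
# polarizability   Charton & Charton (1982) polarizability parameter; normalized scale,
#                  range ~0.00-0.41 (glycine 0, tryptophan max).
# steric_parameter graph shape index encoding side-chain complexity/branching/symmetry
#                  (Fauchere et al. 1988); dimensionless.
# n_h_donors       side-chain hydrogen-bond donor site count (Fauchere et al. 1988).
# n_h_acceptors    side-chain hydrogen-bond acceptor atom count (carbonyl/carboxylate O,
#                  hydroxyl O, thioether/thiol S, unprotonated ring N).
# vdw_volume       normalized side-chain van der Waals volume (Fauchere et al. 1988).
aa	hydrophobicity	polarizability	steric_parameter	n_h_donors	n_h_acceptors	vdw_volume
A	0.31	0.046	1.28	0	0	1.00
R	-1.01	0.291	2.34	4	0	6.13
N	-0.60	0.134	1.60	2	1	2.95
D	-0.77	0.105	1.60	1	2	2.78
C	1.54	0.128	1.77	1	1	2.43
Q	-0.22	0.180	1.56	2	1	3.95
E	-0.64	0.151	1.56	1	2	3.78
G	0.00	0.000	0.00	0	0	0.00
H	0.13	0.230	2.99	1	1	4.66
I	1.80	0.186	4.19	0	0	4.00
L	1.70	0.186	2.59	0	0	4.00
K	-0.99	0.219	1.89	2	0	4.77
M	1.23	0.221	2.35	0	1	4.43
F	1.79	0.290	2.94	0	0	5.89
P	0.72	0.131	2.67	0	0	2.72
S	-0.04	0.062	1.31	1	1	1.60
T	0.26	0.108	3.03	1	1	2.60
W	2.25	0.409	3.21	1	0	8.08
Y	0.96	0.298	2.94	1	1	6.47
V	1.22	0.140	3.67	0	0	3.00
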