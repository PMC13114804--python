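Gene	log2FC	adj.P.Val	P.Value	Gene.Title
LRRN3	2.4062	0.00307	0.00000048	leucine rich repeat neuronal 3
NOG	3.692941	0.00827	0.00000401	noggin
LOC200772	2.204969	0.00827	0.0000046	uncharacterized LOC200772
IGIP	1.346284	0.00827	0.0000039	IgA-inducing protein
LOC105370746	2.031239	0.00914	0.00000686	uncharacterized LOC105370746
GAL3ST4	2.35764	0.01066	0.0000093	galactose-3-O-sulfotransferase 4
TECTB	1.895368	0.01066	0.0000101	tectorin beta
EP400	1.849215	0.01393	0.0000189	E1A binding protein p400
RPARP-AS1	1.241928	0.01406	0.0000193	RPARP antisense RNA 1
HIPK2	1.663838	0.01451	0.0000207	homeodomain interacting protein kinase 2
CCNL1	-3.25661	0.00268	0.000000297	cyclin L1
LOC286059	-2.4506	0.00268	0.000000206	tumor necrosis factor receptor superfamily member 10d decoy with truncated death domain pseudogene
TANK	-2.13701	0.00268	0.0000003	TRAF family member associated NFKB activator
ACAA2	-1.94937	0.00268	0.000000153	acetyl-CoA acyltransferase 2
C6ORF62	-1.4424	0.00268	0.000000343	chromosome 6 open reading frame 62
CXCL8	-4.9294	0.00307	0.000000618	C-X-C motif chemokine ligand 8
SKIL	-2.19999	0.00307	0.000000566	SKI-like proto-oncogene
KLF3	-1.38203	0.00307	0.000000505	Kruppel-like factor 3
CST8	-3.15706	0.00439	0.000000964	cystatin 8
GLUL	-2.73383	0.00629	0.00000161	glutamate-ammonia ligase
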