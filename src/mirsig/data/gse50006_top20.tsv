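Gene	log2FC	adj.P.Val	P.Value	Gene.Title
ABCA6	5.805	1.43E-64	2.62E-69	ATP-binding cassette subfamily A member 6
CCDC88A	3.661	5.79E-59	2.12E-63	coiled-coil domain containing 88A
ADTRP	5.785	3.42E-53	2.50E-57	androgen-dependent TFPI-regulating protein
TRAC	3.385	6.13E-51	7.85E-55	T-cell receptor alpha constant
RASGRF1	4.484	6.75E-49	1.11E-52	Ras protein-specific guanine nucleotide releaser factor 1
PIGR	4.855	1.34E-48	2.44E-52	polymeric immunoglobulin receptor
LEF1	3.942	5.66E-48	1.24E-51	lymphoid enhancer binding factor 1
LAX1	1.648	7.37E-47	2.02E-50	lymphocyte transmembrane adaptor 1
YME1L1	3.562	9.83E-46	2.88E-49	YME1-like 1 ATPase
ROR1	4.528	2.59E-44	8.05E-48	receptor tyrosine kinase-like orphan receptor 1
SCN3A	-6.473	7.48E-57	4.10E-61	sodium voltage-gated channel alpha subunit 3
IGLC1	-5.076	4.52E-53	4.13E-57	immunoglobulin lambda constant 1
IGLJ3	-5.795	7.37E-47	2.01E-50	immunoglobulin lambda joining 3
PARM1	-4.918	1.10E-42	4.21E-46	prostate androgen-regulated mucin-like protein 1
EIF2AK3	-2.609	5.99E-41	2.85E-44	eukaryotic translation initiation factor 2 alpha kinase 3
PMEPA1	-5.176	7.64E-41	4.05E-44	prostate transmembrane protein, androgen induced 1
CXORF57	-4.722	1.97E-39	1.31E-42	chromosome X open reading frame 57
CD55	-1.243	2.69E-39	1.87E-42	CD55 molecule (Cromer blood group)
SNX22	-2.446	3.94E-39	2.81E-42	sorting nexin 22
IGLV1-44	-5.958	6.45E-38	4.83E-41	immunoglobulin lambda variable 1-44
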