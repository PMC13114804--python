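Gene	log2FC	adj.P.Val	P.Value	Gene.Title
CCDC88A	3.398	3.46E-56	2.53E-60	coiled-coil domain containing 88A
ABCA6	5.202	4.51E-55	4.13E-59	ATP-binding cassette subfamily A member 6
TRAC	3.195	5.36E-49	1.27E-52	T-cell receptor alpha constant
LEF1	4.204	4.36E-48	1.2E-51	lymphoid enhancer binding factor 1
PIGR	4.112	2.29E-45	8.39E-49	polymeric immunoglobulin receptor
LAX1	1.810	1.74E-44	6.66E-48	lymphocyte transmembrane adaptor 1
ADTRP	5.641	2.76E-44	1.11E-47	androgen-dependent TFPI-regulating protein
YME1L1	2.3708	9.79E-42	5.01E-45	YME1-like 1 ATPase
TEAD2	2.356	5.86E-40	3.86E-43	TEA domain transcription factor 2
RASGRF1	2.598	1.65E-39	1.21E-42	Ras protein-specific guanine nucleotide-releasing factor 1
SCN3A	-4.248	1.51E-93	2.77E-98	sodium voltage-gated channel alpha subunit 3
IGLJ3	-2.861	4.07E-59	1.49E-63	immunoglobulin lambda joining 3
SLC38A11	-2.651	6.37E-55	6.99E-59	solute carrier family 38 member 11
CORO2B	-2.414	4.08E-54	5.97E-58	coronin 2B
PIK3C2B	-1.959	2.12E-50	3.49E-54	phosphatidylinositol-4-phosphate 3-kinase catalytic subunit type 2 beta
IGHV4-31	-2.445	2.77E-50	5.06E-54	immunoglobulin heavy variable 4-31
PARM1	-2.372	2.29E-47	6.7E-51	prostate androgen-regulated mucin-like protein 1
MIR631	-1.530	2.65E-47	8.25E-51	microRNA 631
SNX29P1	-2.997	3.66E-46	1.2E-49	sorting nexin 29 pseudogene 1
DSP	-2.988	2.28E-45	7.94E-49	desmoplakin
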