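Gene	log2FC	adj.P.Val	P.Value	Gene.Title
PRKCI	1.305649	0.000826	1.51E-8	protein kinase C iota
OGDH	1.76606	0.055421	4.03E-6	oxoglutarate dehydrogenase
IGHD	2.371367	0.064423	1.18E-5	immunoglobulin heavy constant delta
RBL2	1.121092	0.064423	9.11E-6	RB transcriptional corepressor like 2
FCER1A	3.568011	0.07136	1.74E-5	Fc fragment of IgE receptor Ia
FAM30A	3.015036	0.072196	2.51E-5	family with sequence similarity 30, member A
ANKRD30B	2.447083	0.073376	3.22E-5	ankyrin repeat domain 30B
SLC40A1	1.971986	0.073376	3.22E-5	solute carrier family 40 member 1
FAM71A	1.861581	0.073376	3.06E-5	family with sequence similarity 71 member A
PVR	2.262421	0.091305	5.01E-5	poliovirus receptor
SPRR3	-2.67678	0.055421	5.58E-6	small proline rich protein 3
SOHLH1	-2.45603	0.055421	2.11E-6	spermatogenesis and oogenesis specific basic helix-loop-helix 1
OLAH	-1.35534	0.055421	6.08E-6	oleoyl-ACP hydrolase
CCDC148	-2.77283	0.064423	1.16E-5	coiled-coil domain containing 148
NPRL3	-2.05894	0.064423	1.18E-5	NPR3 like, GATOR1 complex subunit
HBB	-4.24573	0.065746	1.44E-5	hemoglobin subunit beta
CEP41	-2.33361	0.07136	1.97E-5	centrosomal protein 41
EIF1B-AS1	-1.94476	0.07136	2.09E-5	EIF1B antisense RNA 1
JAM3	-1.63153	0.07136	1.88E-5	junctional adhesion molecule 3
LINC01419	-2.38925	0.072196	0.000024	long intergenic non-protein coding RNA 1419
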