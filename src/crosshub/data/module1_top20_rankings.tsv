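rank	betweenness	closeness	degree	mcc
1	ACTB	ACTB	ACTB	PSMA1
2	CDC42	CDC42	CDC42	PSMD2
3	RUNX2	HSPA8	RUNX2	PSMC1
4	HSPA8	RUNX2	GFAP	PSME3
5	GFAP	CAV1	HSPA8	PSMB3
6	ITGA2B	GFAP	CAV1	ACTB
7	CAV1	MAPK8	GNB1	RUNX2
8	SNRNP70	PTGS2	PSMD2	POSTN
9	RBX1	VAMP2	MAPK8	ELN
10	GNB1	PRKCZ	ITGA2B	SPARC
11	VAMP2	PIK3CG	PSMA1	ACAN
12	PIK3CG	ITGA2B	PTGS2	SPRED1
13	MAPK8	WNT4	ACAN	TP73
14	FKBP1A	RBX1	PSME3	TIMP3
15	MYL6B	ACAN	RBX1	OAZ1
16	PSMD2	PGR	TRPV1	MAPK6
17	SLC12A1	PSMD2	PSMB3	GFAP
18	ABCC8	GNB1	PSMC1	CDC42
19	OAZ1	TRPV1	KCNA1	HSPA8
20	HMBS	MAP2K3	VAMP2	SDC4
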