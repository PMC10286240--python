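rank	betweenness	closeness	degree	mcc
1	SRC	STAT3	STAT3	NDUFA6
2	CFTR	DLG4	CDH1	UQCRH
3	CAV1	CAV1	BDNF	ATP5MF
4	ACTB	ACTB	MMP9	NDUFB7
5	EGF	ERBB2	EGFR	NDUFV2
6	BDNF	BDNF	ALB	ATP5PO
7	ALB	ALB	AKT1	NDUFC2
8	ITGB1	ITGB1	ITGB1	NDUFB6
9	TP53	TP53	TP53	P13073
10	INS	INS	INS	UQCRC1
11	CDC42	CDC42	CD4	ATP5PD
12	CYCS	EGF	DLG4	COX5A
13	AKT1	AKT1	ACTB	NDUFB9
14	CDH1	CDH1	CDC42	ATP5ME
15	FN1	FN1	FN1	UQCR10
16	SNCA	SRC	SRC	ATP5PF
17	EGFR	ESR1	ERBB2	NDUFA12
18	GAPDH	GAPDH	GAPDH	NDUFA8
19	DLG4	EGFR	EGF	NDUFV1
20	CD4	CD4	CAV1	ATP5MG
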