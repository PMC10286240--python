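gene
AKT1
ALB
BDNF
CAV1
CD4
CDC42
CDH1
DLG4
EGF
EGFR
FN1
GAPDH
INS
ITGB1
ACTB
SRC
TP53
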