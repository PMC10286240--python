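gene
ACTB
CDC42
RUNX2
HSPA8
PSMD2
GFAP
VAMP2
MAPK8
CAV1
GNB1
RBX1
ITGA2B
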