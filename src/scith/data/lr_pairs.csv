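ligand,receptor
TGFB1,TGFBR1
TGFB1,TGFBR2
IL6,IL6R
IL1B,IL1R1
IL10,IL10RA
TNF,TNFRSF1A
CXCL12,CXCR4
CCL2,CCR2
CCL5,CCR5
CX3CL1,CX3CR1
CSF1,CSF1R
VEGFA,KDR
VEGFA,FLT1
EGF,EGFR
HGF,MET
FN1,ITGB1
COL1A1,ITGB1
SPP1,CD44
CD40LG,CD40
ICOSLG,ICOS
CD274,PDCD1
LGALS9,HAVCR2
ANXA1,FPR1
MIF,CD74
GAS6,AXL
JAG1,NOTCH1
DLL4,NOTCH1
WNT5A,FZD5
PGF,FLT1
ANGPT2,TEK
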