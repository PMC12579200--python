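ALPK3
ALS2CR12
BCL9L
BRD3
C9ORF50
CEP55
CYP51A1
DSC2
FOLH1
OBSCN
PEX3
PNKD
TIFAB
VPS13B
ZNF469
ZNF669
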