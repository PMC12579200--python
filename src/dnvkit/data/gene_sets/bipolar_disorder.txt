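ALPK3
ANKRD13B
BCL9L
BRD3
CEP55
COL21A1
DSC2
FOLH1
KAZN
PURG
RALGAPA2
SLC22A17
VPS13B
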