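ADAMTS16
ALS2CR12
BRD3
CEP55
COL21A1
KLHL29
NUP133
PURG
RALGAPA2
SPATA6
TIFAB
TNFRSF10A
VPS13B
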