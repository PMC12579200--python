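ALPK3
BCL9L
BRD3
C2ORF71
CACTIN
CEP55
COL21A1
CYP51A1
FBXO42
FOLH1
INTS1
KAZN
KLHL29
KNSTRN
RALGAPA2
SLC22A17
SRSF6
TNFRSF10A
ZFP57
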