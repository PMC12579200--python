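BRD3
C2ORF71
CEP55
FOLH1
INTS1
KLHL29
PNKD
PURG
RALGAPA2
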