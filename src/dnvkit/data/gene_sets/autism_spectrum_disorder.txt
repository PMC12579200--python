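ALPK3
ALS2CR12
BCL9L
CACTIN
COL21A1
INTS1
KAZN
KLHL29
KNSTRN
OBSCN
PURG
RALGAPA2
ZFP57
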