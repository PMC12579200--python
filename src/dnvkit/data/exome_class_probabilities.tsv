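gene	class	probability
EXOME_AGGREGATE	missense	0.3148148148
EXOME_AGGREGATE	splice	0.00744047619
EXOME_AGGREGATE	synonymous	0.1398880895
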