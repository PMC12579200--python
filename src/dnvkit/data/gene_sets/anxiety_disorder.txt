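ALS2CR12
ANKRD13B
FOLH1
KNSTRN
VPS13B
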