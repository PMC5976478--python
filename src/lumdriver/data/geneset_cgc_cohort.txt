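CIITA
PIK3CA
POLD1
PRKAR1A
TP53
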