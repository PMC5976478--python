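PTEN
ATR
RBM16/SCAF8
PLCG2
UBR5
ARID1A
TCF20
CFTR
MAP2K4
SH3PXD2A
RB1
ATXN2
DIP2B
KIAA2026
PCNX1
PHF2
TNKS2
SLC9A1
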