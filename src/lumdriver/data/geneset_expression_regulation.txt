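GRIN1
GRHL2
CTCFL
PTEN
VIM
GATA3
NARG2/ICE2
KMT2A
NTRK2
NR1I3
ITGA8
MTA2
NFKBIA
ATF7IP
SPAG8
TARBP2
TLR3
ARID1A
IRF7
TCF20
THOC5
RB1
NFYB
TRAF5
JHDM1D/KDM7A
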