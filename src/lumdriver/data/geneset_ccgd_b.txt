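GATA3
ZMYND11
DNAH17
NEMF
BTBD7
ITGB1
KLHDC2
MTA2
ODF2
PCCA
PPFIA3
RASGRF1
NBR1
PRDM5
NFYB
THOC5
CLMN
KIAA0947/ICE1
OSBPL1A
RAB11A
ARHGAP29
SLTM
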