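protein
MESPA
MESPB
MSGN1
EBF2
NEUROD6
NEUROD4
NEUROD2
NEUROD1
NEUROG1
NEUROG3
NHLH1
TCF21
TCF12
TCF4
TFEB
TFE3
HES4
HES5.1
HES7.1
HES1
DLL1
SIM1
SIM2
ID2
ID3
ID4
MYF6
MYF5
MYOG
MYOD1
NOTCH1
OLIG2
OLIG3
OLIG4
LYL1
HEY1
HEY2
TWIST1
HAND1
HAND2
MEF2C
MGC75596
MLX
MXI1
MAX
LMYC1
MNT
MYC
PTF1A
TAL1
MSC
TAL2
ATOH1
ATOH7
ARNT
ARNT2
AHR1
BHLHE40
BHLHE41
HIF1A
VHL
CLOCK
EPAS1
CARM1
NCOA1
NCOA2
NCOA3
SREBF2
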