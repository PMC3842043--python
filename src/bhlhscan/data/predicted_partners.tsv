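protein
CARM1
INSIG2
MEF2C
VHL
INSIG1
MGC75596
NOTCH1
DLL1
SCAP
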