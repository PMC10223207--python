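trait,k,p_value
SVMP,0.566,0.405
SVSP,0.932,0.026
PLA2,0.728,0.158
CRISP,0.789,0.153
Disintegrin,0.324,0.694
BPP/CNP,0.474,0.422
CTL,0.628,0.303
LAAO,0.499,0.504
Venom breadth,0.472,0.492
LD50,0.621,0.311
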