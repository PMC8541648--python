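>osa-miR156a MIR156 Oryza sativa; transcribed from miRBase 22
UGACAGAAGAGAGUGAGCAC
>ath-miR156a-5p MIR156 Arabidopsis thaliana; transcribed from miRBase 22
UGACAGAAGAGAGUGAGCAC
>zma-miR156a-5p MIR156 Zea mays; transcribed from miRBase 22
UGACAGAAGAGAGUGAGCAC
>osa-miR529a MIR529 Oryza sativa; transcribed from miRBase 22
AGAAGAGAGAGAGUACAGCCU
>zma-miR529-5p MIR529 Zea mays; transcribed from miRBase 22
AGAAGAGAGAGAGUACAGCUU
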