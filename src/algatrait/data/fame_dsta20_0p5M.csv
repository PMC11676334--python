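label,weight_percent
Myristic acid (C14:0),0.49
Palmitic acid (C16:0),21.06
Palmitoleic acid (C16:1 w-7),1.63
Hexadecadienoic acid (C16:2 w-6),1.08
Hexadecatrienoic acid (C16:3 w-3),2.75
Hexadecatetraenoic acid (C16:4 w-3),13.23
Stearic acid (C18:0),0.53
Oleic acid (C18:1 w-9),2.77
Linoleic acid (C18:2 w-6),6.81
gamma-linolenic acid (C18:3 w-6),3.84
alpha-linolenic acid (C18:3 w-3),31.55
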