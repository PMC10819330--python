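residue,residue_type,hbv
Gln63,Uncharged,11.50
His201,Positive,10.33
Arg252,Positive,10.00
Arg195,Positive,6.06
His299,Positive,5.19
Asp356,Negative,5.18
Gly308,Uncharged,4.72
Arg291,Positive,4.45
Gly306,Uncharged,4.34
His305,Positive,4.30
Thr52,Uncharged,4.20
Asp300,Negative,4.19
Tyr151,Uncharged,3.85
Lys200,Positive,3.59
Asp197,Negative,3.29
Ser289,Uncharged,3.05
Trp59,Nonpolar,2.87
Trp280,Nonpolar,2.12
Gln161,Uncharged,2.06
Glu233,Negative,2.06
Glu240,Negative,2.03
Asn53,Uncharged,2.00
Tyr2,Uncharged,1.75
Ala3,Nonpolar,1.67
Gly106,Uncharged,1.59
Ser311,Uncharged,1.59
Gly9,Uncharged,1.52
Ser310,Uncharged,1.40
Ala107,Nonpolar,1.25
Pca1,,1.06
Val354,Nonpolar,1.06
Asp402,Negative,1.06
Ile148,Nonpolar,1.03
Asn152,Uncharged,1.03
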