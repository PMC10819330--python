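amino_acid,residue_type,peptide_id,position,hbv
A,Nonpolar,7,6,1.40
A,Nonpolar,19,2,3.42
A,Nonpolar,20,11,2.99
D,Negative,1,5,6.00
D,Negative,8,6,1.40
D,Negative,13,3,2.84
E,Negative,1,1,1.59
E,Negative,12,4,1.59
E,Negative,13,4,1.84
E,Negative,16,1,1.59
E,Negative,18,2,2.94
E,Negative,20,5,1.00
F,Nonpolar,2,5,5.35
F,Nonpolar,7,8,6.34
G,Uncharged,14,6,1.52
G,Uncharged,15,10,1.52
G,Uncharged,15,8,1.59
G,Uncharged,15,12,2.12
G,Uncharged,17,8,1.40
G,Uncharged,17,10,1.35
G,Uncharged,18,4,1.30
G,Uncharged,20,7,1.75
H,Positive,3,3,1.35
H,Positive,4,3,1.46
H,Positive,6,5,2.70
H,Positive,14,10,2.86
H,Positive,15,6,1.52
H,Positive,17,9,1.35
I,Nonpolar,11,1,1.00
K,Positive,2,1,1.09
L,Nonpolar,6,2,1.46
L,Nonpolar,6,7,1.30
M,Nonpolar,19,16,1.06
M,Nonpolar,20,16,3.65
N,Uncharged,13,6,1.00
N,Uncharged,14,3,3.15
P,Nonpolar,2,3,1.59
P,Nonpolar,3,6,3.78
P,Nonpolar,3,6,3.78
P,Nonpolar,4,7,1.06
P,Nonpolar,6,1,1.06
P,Nonpolar,6,8,1.59
P,Nonpolar,11,10,5.20
R,Positive,5,6,1.84
R,Positive,5,8,1.03
R,Positive,8,1,3.09
R,Positive,10,4,1.06
R,Positive,12,2,1.94
R,Positive,12,10,1.00
R,Positive,13,10,3.93
S,Uncharged,12,9,1.35
S,Uncharged,19,14,2.86
S,Uncharged,20,2,1.35
S,Uncharged,20,3,1.25
T,Uncharged,17,14,3.82
V,Nonpolar,17,4,1.30
W,Nonpolar,12,8,1.94
W,Nonpolar,19,6,1.06
Y,Uncharged,13,1,1.00
Y,Uncharged,14,1,3.65
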