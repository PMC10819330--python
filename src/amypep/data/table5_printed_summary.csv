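amino_acid,residue_type,n_occurrences,total,mean,letters
A,Nonpolar,13,7.81,0.60,ab
D,Negative,3,10.24,3.41,a
E,Negative,10,10.55,1.06,ab
F,Nonpolar,8,11.69,1.46,ab
G,Uncharged,37,12.55,0.34,ab
H,Positive,9,11.23,1.25,ab
I,Nonpolar,6,1.00,0.17,ab
K,Positive,1,1.09,1.09,ab
L,Nonpolar,26,6.00,0.23,b
M,Nonpolar,8,4.71,0.59,ab
N,Uncharged,6,4.15,0.69,ab
P,Nonpolar,28,18.06,0.65,ab
R,Positive,8,12.06,1.51,a
S,Uncharged,9,6.80,0.76,ab
T,Uncharged,4,3.82,0.96,ab
V,Nonpolar,10,1.30,0.13,ab
W,Nonpolar,3,3.01,1.00,ab
Y,Uncharged,3,4.65,1.55,ab
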