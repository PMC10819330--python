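peptide_id,sequence,r_n,f
1,EAGVD,0.814,1.000
2,KLPGF,0.741,0.867
3,PPHMLP,0.864,0.774
4,PPHMGGP,0.719,0.719
5,LPLPLPLR,0.898,0.761
6,PLPLHMLP,0.495,0.563
7,PLPWGAGF,0.957,0.901
8,RALPIDVL,0.141,0.869
10,RLARAGLAQ,0.375,0.250
11,IPLPLPLPLP,0.760,1.000
12,LRSELAAWSR,0.684,0.693
13,YFDEQNEQFR,0.540,0.666
14,YGNPVGGVGH,0.347,0.780
15,GQLGEHGGAGMG,0.815,0.628
16,EQGFLPGPEESGR,0.000,1.000
17,GNPVGGVGHGTTGT,0.735,0.592
18,GEHGGAGMGGGQFQPV,0.115,0.754
19,HAGPTWNPISIGISFM,0.572,0.722
20,LSSLEMGSLGALFVCM,0.583,0.662
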