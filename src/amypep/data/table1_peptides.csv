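id,sequence,ic50,source
1,EAGVD,110.00,Egg
2,KLPGF,120.00,Egg
3,PPHMLP,103.69,Pinto bean
4,PPHMGGP,88.13,Pinto bean
5,LPLPLPLR,446.54,Camel milk
6,PLPLHMLP,70.22,Pinto bean
7,PLPWGAGF,69.91,Pinto bean
8,RALPIDVL,24.27,Oat bran
9,NINAHSVVY,22.43,Oat bran
10,RLARAGLAQ,69.88,Millet grain
11,IPLPLPLPLP,364.70,Camel milk
12,LRSELAAWSR,527.80,Spirulina platensis
13,YFDEQNEQFR,12.50,Oat bran
14,YGNPVGGVGH,80.28,Millet grain
15,GQLGEHGGAGMG,53.00,Millet grain
16,EQGFLPGPEESGR,51.09,Millet grain
17,GNPVGGVGHGTTGT,50.01,Millet grain
18,GEHGGAGMGGGQFQPV,44.58,Millet grain
19,HAGPTWNPISIGISFM,387.74,Camel milk
20,LSSLEMGSLGALFVCM,44.58,Pinto bean
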