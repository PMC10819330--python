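residue,residue_type,in_count
His201,Positive,15
Gln63,Uncharged,15
Asp300,Negative,14
His305,Positive,14
His299,Positive,12
Val163,Nonpolar,11
Trp59,Nonpolar,10
Asp197,Negative,10
Tyr151,Uncharged,10
Glu233,Negative,9
Lys200,Positive,9
Arg195,Positive,9
His101,Positive,8
Asp356,Negative,8
Leu162,Nonpolar,7
Tyr62,Uncharged,6
Ile235,Nonpolar,6
Ala307,Nonpolar,6
Ile148,Nonpolar,4
Gly306,Uncharged,4
Gly308,Uncharged,4
Trp58,Nonpolar,3
Gly309,Uncharged,3
Asp402,Negative,3
Asn53,Uncharged,3
Ser289,Uncharged,3
Arg252,Positive,3
Thr6,Uncharged,2
Ser105,Uncharged,2
Ala198,Nonpolar,2
His331,Positive,2
Glu352,Negative,2
Arg398,Positive,2
Phe406,Nonpolar,2
Arg421,Positive,2
Glu282,Negative,2
Gly9,Uncharged,2
Gly106,Uncharged,2
Tyr2,Uncharged,2
Glu240,Negative,2
Gln161,Uncharged,2
Trp280,Nonpolar,2
Arg291,Positive,2
Gln5,Uncharged,1
Ser8,Uncharged,1
Thr11,Uncharged,1
Val50,Nonpolar,1
Val51,Nonpolar,1
Pro54,Nonpolar,1
Glu149,Negative,1
Gly164,Uncharged,1
Leu165,Nonpolar,1
Ser226,Uncharged,1
Arg227,Positive,1
Ala241,Nonpolar,1
Thr264,Uncharged,1
Ser270,Uncharged,1
Glu272,Negative,1
Asp290,Negative,1
Phe335,Nonpolar,1
Gly403,Uncharged,1
Asn152,Uncharged,1
Pca1,,1
Val354,Nonpolar,1
Ala107,Nonpolar,1
Ser310,Uncharged,1
Ser311,Uncharged,1
Ala3,Nonpolar,1
Thr52,Uncharged,1
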