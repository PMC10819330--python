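metric,side_chain_type,n_residues,total,mean,letters
IN,Nonpolar,19,62,3.26,
IN,Uncharged,26,72,2.77,
IN,Positive,12,79,6.58,
IN,Negative,11,63,5.73,
HBV,Nonpolar,6,10.00,1.67,b
HBV,Uncharged,14,44.60,3.19,ab
HBV,Positive,8,46.67,5.83,a
HBV,Negative,7,18.81,2.69,ab
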