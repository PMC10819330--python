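side_chain_type,n_residues,total,mean,letters
Nonpolar,102,50.32,0.49,b
Uncharged,59,31.97,0.54,b
Positive,18,26.22,1.46,a
Negative,13,20.79,1.60,a
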