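name	mibig_id	backbone	citation
Delftibactin	BGC0000984	pk(NH2+ohmal),Asp,Thr,Gly,Thr(mod),Orn(mod),Ser,Arg,Orn(cyclic)	Johnston et al. 2013 Nat Chem Biol 9:241-243
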