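# Monomer synonym table: raw spelling (lowercased, modifications already
# stripped) -> canonical token.  Extend this file to absorb further
# KEGG / Norine / antiSMASH spelling variants; tokens already canonical
# need no row.  Tab-separated, '#' starts a comment.
alanine	ala
arginine	arg
asparagine	asn
aspartate	asp
aspartic acid	asp
cysteine	cys
glutamate	glu
glutamic acid	glu
glutamine	gln
glycine	gly
histidine	his
isoleucine	ile
leucine	leu
lysine	lys
methionine	met
phenylalanine	phe
proline	pro
serine	ser
threonine	thr
tryptophan	trp
tyrosine	tyr
valine	val
ornithine	orn
2,4-diaminobutyric acid	dab
diaminobutyrate	dab
malonyl	mal
malonyl-coa	mal
methylmalonyl	mmal
methoxymalonyl	mxmal
ethylmalonyl	emal
hydroxymalonyl	ohmal
polyketide	pk
x	nrp
unknown	nrp
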