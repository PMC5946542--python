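# The six snake mitogenome arrangements reported before this analysis
# (typical-minus-OL blind-snake orders, the common alethinophidian order,
# the viperid order, its pseudo-Pro variant, and the colubrid/homalopsid
# pseudo-Pro order). Dialect as in arrangement_types.tsv.
label	role	requires_cr_asymmetry	description	order
PRIOR-A	type	0	Brahminy blind snake order: typical arrangement without OL	F,12S,V,16S,L2,ND1,I,-Q,M,ND2,W,-A,-N,-C,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,-P,CR
PRIOR-B	type	0	Texas blind snake order: OL lost, tRNA-Gln inside WANCY	F,12S,V,16S,L2,ND1,I,M,ND2,W,-Q,-A,-N,-C,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,-P,CR
PRIOR-C	type	0	Common alethinophidian order: duplicate CR in IQM, tRNA-Leu(UUR) 3' of CR2	F,12S,V,16S,ND1,I,CR,L2,-Q,M,ND2,W,-A,-N,OL,-C,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,-P,CR
PRIOR-D	type	0	Viperid order: tRNA-Pro 5' of CR2	F,12S,V,16S,ND1,I,-P,CR,L2,-Q,M,ND2,W,-A,-N,OL,-C,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,CR
PRIOR-E	type	0	Viperid order with pseudo-Pro 5' of CR1	F,12S,V,16S,ND1,I,-P,CR,L2,-Q,M,ND2,W,-A,-N,OL,-C,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,-P*,CR
PRIOR-F	type	0	Colubrid/homalopsid order with pseudo-Pro 5' of CR2	F,12S,V,16S,ND1,I,-P*,CR,L2,-Q,M,ND2,W,-A,-N,OL,-C,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,-P,CR
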