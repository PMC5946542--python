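# Reference mitogenome arrangements for snakes: the canonical squamate
# baseline plus the eleven snake arrangement types. Token dialect:
# "-" prefix = L-strand, ":N" suffix = length in bp, "*" suffix = pseudogene.
# CR1 = ancestral-position control region (5' of tRNA-Phe); CR2 = duplicated
# copy inside the IQM cluster. In the F-anchored strings below CR2 therefore
# appears first and CR1 last.
label	role	requires_cr_asymmetry	description	order
CANONICAL	reference	0	Typical squamate order: IQM cluster, WAN-OL-CY cluster, single CR between tRNA-Pro and tRNA-Phe	F,12S,V,16S,L2,ND1,I,-Q,M,ND2,W,-A,-N,OL,-C,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,-P,CR
I	type	0	Single CR; OL lost; tRNA-Gln translocated from IQM into WANCY (WQANCY)	F,12S,V,16S,L2,ND1,I,M,ND2,W,-Q,-A,-N,-C,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,-P,CR
II	type	0	Single CR; OL lost from the WANCY cluster; otherwise typical order	F,12S,V,16S,L2,ND1,I,-Q,M,ND2,W,-A,-N,-C,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,-P,CR
III	type	0	Duplicated CR inside the IQM cluster; tRNA-Leu(UUR) translocated 3' of CR2	F,12S,V,16S,ND1,I,CR,L2,-Q,M,ND2,W,-A,-N,OL,-C,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,-P,CR
III-A	type	0	Type III with tRNA-Lys translocated from 3' of COX2 to 5' of ATP6	F,12S,V,16S,ND1,I,CR,L2,-Q,M,ND2,W,-A,-N,OL,-C,-Y,COX1,-S2,D,COX2,ATP8,K,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,-P,CR
III-B	type	0	Type III with tRNA-Pro translocated to 5' of CR2	F,12S,V,16S,ND1,I,-P,CR,L2,-Q,M,ND2,W,-A,-N,OL,-C,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,CR
III-B1	type	0	Type III-B with a pseudo-Pro inserted 5' of CR1	F,12S,V,16S,ND1,I,-P,CR,L2,-Q,M,ND2,W,-A,-N,OL,-C,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,-P*,CR
III-C	type	0	Type III with a pseudo-Pro inserted 5' of CR2	F,12S,V,16S,ND1,I,-P*,CR,L2,-Q,M,ND2,W,-A,-N,OL,-C,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,-P,CR
III-D	type	0	Type III with an extra tRNA-Ile (copied from 3' of ND1) inserted 5' of CR1	F,12S,V,16S,ND1,I,CR,L2,-Q,M,ND2,W,-A,-N,OL,-C,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,-P,I,CR
III-E	type	1	Type III token order with strongly asymmetric control regions (CR1 2878 bp, CR2 4110 bp)	F,12S,V,16S,ND1,I,CR:4110,L2,-Q,M,ND2,W,-A,-N,OL,-C,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,-P,CR:2878
III-F	type	0	Type III with a 342 bp non-coding insertion between ND5 and ND6, control regions asymmetric	F,12S,V,16S,ND1,I,CR:2200,L2,-Q,M,ND2,W,-A,-N,OL,-C,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,NC:342,-ND6,-E,CYTB,T,-P,CR:1100
III-G	type	0	Type III with a 5702 bp non-coding insertion between tRNA-Cys and tRNA-Tyr	F,12S,V,16S,ND1,I,CR,L2,-Q,M,ND2,W,-A,-N,OL,-C,NC:5702,-Y,COX1,-S2,D,COX2,K,ATP8,ATP6,COX3,G,ND3,R,ND4L,ND4,H,S1,L1,ND5,-ND6,-E,CYTB,T,-P,CR
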