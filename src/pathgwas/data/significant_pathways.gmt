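REACTOME_SIGNALING_BY_PDGF	Reactome	HRAS	PDGFB	PDGFA	BCAR1	STAT5A	STAT5B	PIK3CA	PDGFC	PDGFD	RAPGEF1	PIK3CB	MAPK1	NCK2	CRKL	NCK1	MAPK3	COL1A2	PDGFRA	PDGFRB	COL1A1	GRB2	COL3A1	COL2A1	SRC	STAT6	COL9A1	COL9A2	COL9A3	KRAS	COL6A6	SOS1	COL6A3	COL6A2	COL6A1	THBS1	THBS2	PIK3R1	THBS3	RASA1	PIK3R2	THBS4	SPP1	COL4A4	PLAT	COL4A3	COL4A2	COL4A1	MAP2K1	MAP2K2	YWHAB	RAF1	STAT1	COL5A2	FURIN	PLG	STAT3	COL5A1	COL4A5	PTPN11	NRAS	PLCG1	COL29A1	CRK	GRB7
REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH	Reactome	NRTN	HRAS	GDNF	ARTN	NCAM1	MAPK1	MAPK3	CNTN2	COL1A2	COL1A1	PRNP	NCAN	SPTB	FGFR1	GRB2	COL3A1	CACNB1	CACNB2	COL2A1	CACNB3	CACNB4	ST8SIA2	SRC	COL9A1	COL9A2	PTK2	COL9A3	KRAS	COL6A6	SOS1	COL6A3	COL6A2	COL6A1	AGRN	COL4A4	COL4A3	COL4A2	COL4A1	MAP2K1	SPTBN5	MAP2K2	CREB1	CACNA1I	SPTBN4	PTPRA	YWHAB	RAF1	COL5A2	CACNA1S	COL5A1	COL4A5	RPS6KA5	PSPN	NRAS	FYN	ST8SIA4	CACNA1G	SPTBN2	CACNA1H	SPTBN1	GFRA1	COL29A1	SPTA1	CACNA1F	GFRA4	CACNA1C	CACNA1D	GFRA2	SPTAN1
BIOCARTA_RACCYCD_PATHWAY	Biocarta	E2F1	HRAS	NFKBIA	NFKB1	AKT1	CCNE1	RAC1	RHOA	PIK3CA	PAK1	CHUK	PIK3R1	TFDP1	RELA	RAF1	CDK6	RB1	CDK4	CDK2	MAPK1	CCND1	CDKN1A	CDKN1B	IKBKG	MAPK3	IKBKB
BIOCARTA_SKP2E2F_PATHWAY	Biocarta	CDC34	CCNA1	E2F1	CUL1	TFDP1	CDK2	RB1	CCNE1	SKP2	SKP1
REACTOME_UNFOLDED_PROTEIN_RESPONSE	Reactome	HERPUD1	MBTPS2	PDIA6	NFYA	EDEM1	DDIT3	ATF6	ATF4	ATF3	DNAJB9	DNAJB11	XBP1	EIF2S1	ERN1	HSPA5	DNAJC3	MBTPS1	EIF2AK3	SERP1
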