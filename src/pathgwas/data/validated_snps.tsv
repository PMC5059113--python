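pathway	snp_id	gene	maf_case_discovery	maf_control_discovery	p_discovery	maf_case_replication	maf_control_replication	p_replication	maf_case_pooled	maf_control_pooled	p_meta
REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH	rs12416052	CACNB2	0.43	0.40	0.024	0.43	0.41	0.0488	0.43	0.41	0.00638
REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH	rs17611556	CACNB2	0.06	0.09	0.0148	0.06	0.07	0.0185	0.06	0.08	0.00194
REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH	rs1990240	CACNA1C	0.28	0.25	0.0163	0.28	0.26	0.0206	0.28	0.26	0.00229
REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH	rs2239062	CACNA1C	0.44	0.41	0.0194	0.46	0.44	0.0188	0.46	0.44	0.00353
REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH	rs2239117	CACNA1C	0.28	0.25	0.0097	0.28	0.27	0.0452	0.28	0.26	0.00491
REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH	rs2239118	CACNA1C	0.25	0.21	0.0024	0.25	0.23	0.0447	0.25	0.23	0.0024
REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH	rs3767499	CACNA1S	0.50	0.47	0.0325	0.49	0.47	0.0198	0.49	0.47	0.00224
REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH	rs418543	COL4A2	0.37	0.33	0.0098	0.36	0.34	0.0049	0.36	0.34	0.00026
REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH	rs6011959	SRC	0.31	0.28	0.032	0.28	0.26	0.0051	0.29	0.26	0.00019
REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH	rs7132154	CACNA1C	0.24	0.27	0.0313	0.23	0.25	0.0008	0.23	0.26	0.00011
REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH	rs7963955	CACNA1C	0.28	0.25	0.0149	0.28	0.26	0.0219	0.28	0.26	0.00231
REACTOME_SIGNALING_BY_PDGF	rs418543	COL4A2	0.37	0.33	0.0098	0.36	0.34	0.0049	0.36	0.34	0.00026
REACTOME_SIGNALING_BY_PDGF	rs6011959	SRC	0.31	0.28	0.032	0.28	0.26	0.0051	0.29	0.26	0.00019
REACTOME_SIGNALING_BY_PDGF	rs7040470	RAPGEF1	0.42	0.46	0.0089	0.43	0.46	0.0004	0.43	0.46	1.20E-05
BIOCARTA_RACCYCD_PATHWAY	rs4804903	CCNE1	0.30	0.34	0.0019	0.33	0.34	0.0458	0.32	0.34	0.00106
BIOCARTA_RACCYCD_PATHWAY	rs8102137	CCNE1	0.38	0.32	0.0006	0.35	0.33	0.0003	0.36	0.33	1.43E-06
BIOCARTA_RACCYCD_PATHWAY	rs997669	CCNE1	0.44	0.39	0.0019	0.42	0.39	0.0031	0.42	0.39	3.61E-05
BIOCARTA_SKP2E2F_PATHWAY	rs10491321	SKP1	0.16	0.20	0.0035	0.19	0.20	0.0206	0.18	0.20	0.00045
BIOCARTA_SKP2E2F_PATHWAY	rs4804903	CCNE1	0.30	0.34	0.0019	0.33	0.34	0.0458	0.32	0.34	0.00106
BIOCARTA_SKP2E2F_PATHWAY	rs8102137	CCNE1	0.38	0.32	0.0006	0.35	0.33	0.0003	0.36	0.33	1.43E-06
BIOCARTA_SKP2E2F_PATHWAY	rs997669	CCNE1	0.44	0.39	0.0019	0.42	0.39	0.0031	0.42	0.39	3.61E-05
REACTOME_UNFOLDED_PROTEIN_RESPONSE	rs2518054	HERPUD1	0.13	0.11	0.0312	0.11	0.10	0.0193	0.12	0.10	0.00168
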