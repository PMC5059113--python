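pathway	p_gengen	rank_gengen	p_aligator	rank_aligator	p_srt	rank_srt
REACTOME_SIGNALING_BY_PDGF	<0.001	1	0.0264	25	0.005994	5
REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH	<0.001	1	0.0198	21	0.013986	12
BIOCARTA_RACCYCD_PATHWAY	0.001	2	0.0012	2	0.001998	2
BIOCARTA_SKP2E2F_PATHWAY	0.001	2	0.0016	3	0.011988	10
BIOCARTA_NDKDYNAMIN_PATHWAY	0.003	4	0.007	8	0.08991	56
REACTOME_NCAM1_INTERACTIONS	0.005	6	0.009	11	0.025974	21
BIOCARTA_P27_PATHWAY	0.005	6	0.0044	6	0.021978	18
REACTOME_UNFOLDED_PROTEIN_RESPONSE	0.007	8	0.0008	1	0.000999	1
REACTOME_INACTIVATION_OF_APC_VIA_DIRECT_INHIBITION_OF_THE_APCOMPLEX	0.008	9	0.0368	30	0.002997	3
BIOCARTA_BAD_PATHWAY	0.009	10	0.0496	38	0.008991	7
REACTOME_CONVERSION_FROM_APC_CDC20_TO_APC_CDH1_IN_LATE_ANAPHASE	0.013	13	0.0484	37	0.016983	14
BIOCARTA_NFAT_PATHWAY	0.017	16	0.0036	4	0.013986	12
REACTOME_CTLA4_INHIBITORY_SIGNALING	0.018	17	0.0392	32	0.027972	22
REACTOME_PHOSPHORYLATION_OF_THE_APC	0.018	17	0.0376	31	0.010989	9
REACTOME_APCDC20_MEDIATED_DEGRADATION_OF_CYCLIN_B	0.019	18	0.0392	32	0.00999	8
KEGG_PROSTATE_CANCER	0.02	19	0.004	5	0.036963	29
REACTOME_SYNTHESIS_OF_BILE_ACIDS_AND_BILE_SALTS_VIA_24_HYDROXYCHOLESTEROL	0.025	22	0.007	8	0.048951	36
BIOCARTA_DC_PATHWAY	0.044	34	0.0138	17	0.005994	5
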