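patient_id	ancestry	age	psa	isup_gg	gene	sv_id	final_class	vaf	loh	second_hit
N0001	AFR	75	22.9	4	SLC3A1	SLC3A1_DUP	PP_SV_clinvar	0.33	LOH_neg
SMU094	AFR	64	15	4	SLC3A1	SLC3A1_DUP	PP_SV_clinvar	0.30	LOH_CNG	CNL
N0059	AFR	79	153	5	OCA2	OCA2_DEL	PP_SV_clinvar	0.45	LOH_neg	CNG
SMU083	AFR	86	40.5	3	PIGN	PIGN_DEL	PP_SV_clinvar	0.51	LOH_CNL
UP2035	AFR	70	680	5	SLC7A2	SLC7A2_DEL	PP_SV	0.48	LOH_neg	CNL
KAL0054	AFR	64	42.9	5	SLC7A2	SLC7A2_DEL	PP_SV	0.49	LOH_CNG
17135	EUR	63	7.8	5	DNAJC15	DNAJC15_DEL	PP_SV	0.48	LOH_neg
KAL0101	AFR	71	32.3	5	BCL2L11	BCL2L11_DEL	PP_SV	0.45	LOH_CNN
N0073	AFR	62			BARD1	BARD1_DEL	PP_SV	0.49	LOH_CNN
UP2039	AFR	71	319	4	COL4A2/COL4A1	COL4A2_DUP	PP_SV	0.35	LOH_neg
11099	EUR	70	9.9	5	SLC2A5	SLC2A5_DUP	PP_SV	0.33	LOH_neg
UP2101	AFR	57	75	5	FOXP1	FOXP1_INV	PP_SV	0.41	LOH_neg	CNG
N0084	AFR	65	591	4	FOXP1	FOXP1_INV	PP_SV	0.41	LOH_neg
N0048	AFR	70	83.3	5	WASF1	WASF1_INV	PP_SV	0.32	LOH_neg	CNG
SMU080	AFR	64	23.3	4	MLH1	MLH1_INV	PP_SV	0.43	LOH_neg
SMU064	AFR	70	13.7	3	RB1	RB1_INV	PP_SV	0.37	LOH_neg
13179	EUR	59	8.4	5	CTNNA1	CTNNA1_TRA	PP_SV	0.50	LOH_neg
11452	EUR	67	11	1	AK8-DST	AK8_DST_TRA	PP_SV	0.47	LOH_neg
5287	EUR	54	4.3	5	LTBP1/BIRC6	LTBP1_BIRC6_DUP	cautionary	0.39	LOH_neg	CNG
SMU061	AFR	65	12.1	3	PHC3-PRKACA	PHC3_PRKACA_TRA	cautionary	0.49	LOH_neg	CNL
UP2039	AFR	71	319	4	KCTD3-DST	KCTD3_DST_TRA	cautionary	0.40	LOH_neg	CNL
SMU101	AFR	70	4.3	3	KCTD3-DST	KCTD3_DST_TRA	cautionary	0.42	LOH_neg
N0056	AFR	70	153	5	PKHD1	PKHD1_TRA	cautionary	0.36	LOH_neg	CNG
SMU196	AFR	47	9.5	1	PKHD1	PKHD1_TRA	cautionary	0.39	LOH_neg
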