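gene	impact	chrom1	pos1	chrom2	pos2	svtype	dbvar_status	maf_afr	maf_eur	final_class
SLC3A1	IED	chr2	44281377	chr2	44281612	DUP	likely_pathogenic	0.01	0	PP_SV_clinvar
OCA2	pLoF	chr15	28017719	chr15	28020677	DEL	likely_pathogenic	0.004	0	PP_SV_clinvar
PIGN	pLoF	chr18	62152637	chr18	62157701	DEL	pathogenic	0.004	0	PP_SV_clinvar
SLC7A2	pLoF	chr8	17418976	chr8	17544122	DEL	in_dbvar	0.009	0	PP_SV
DNAJC15	pLoF	chr13	43078470	chr13	43079390	DEL	in_dbvar	0	0.009	PP_SV
BCL2L11	pLoF	chr2	111122626	chr2	111125901	DEL	novel	0.005	0	PP_SV
BARD1	pLoF	chr2	214768022	chr2	214772899	DEL	novel	0.005	0	PP_SV
COL4A2/COL4A1	CG	chr13	110294204	chr13	110633815	DUP	in_dbvar	0.005	0	PP_SV
SLC2A5	IED	chr1	9045605	chr1	9049441	DUP	in_dbvar	0	0.009	PP_SV
FOXP1	pLoF	chr3	71097066	chr3	74525618	INV	novel	0.009	0	PP_SV
WASF1	pLoF	chr6	108167886	chr6	110172775	INV	in_dbvar	0.004	0	PP_SV
MLH1	pLoF	chr3	37000362	chr3	39352689	INV	in_dbvar	0.004	0	PP_SV
RB1	pLoF	chr13	48466588	chr13	48473911	INV	in_dbvar	0.004	0	PP_SV
CTNNA1	pLoF	chr5	138903881	chr19	21614900	TRA	novel	0	0.009	PP_SV
AK8-DST	pLoF	chr9	132876361	chr6	56896165	TRA	novel	0	0.009	PP_SV
LTBP1/BIRC6	CG	chr2	32403832	chr2	33107415	DUP	in_dbvar	0	0.009	cautionary
PHC3-PRKACA	pLoF	chr3	170090742	chr19	14110142	TRA	novel	0.004	0	cautionary
KCTD3-DST	pLoF	chr1	215567414	chr6	56652607	TRA	novel	0.009	0	cautionary
PKHD1	pLoF	chr6	51981375	chr15	30874073	TRA	novel	0.009	0	cautionary
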