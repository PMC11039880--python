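molecule_class	feature_id	comparison	fold_change	p
lncRNA	ENSMUST00000151998	siNT-POVPC_vs_siNT-DMSO	-2.88	0.01
lncRNA	ENSMUST00000137236	siOct4-DMSO_vs_siNT-DMSO	-2.47	0.002
lncRNA	ENSMUST00000173605	siOct4-POVPC_vs_siOct4-DMSO	-3.8	0.026
miRNA	mmu-miR-15a-5p	siNT-POVPC_vs_siNT-DMSO	1.59	0.01
miRNA	mmu-miR-322-5p	siNT-POVPC_vs_siNT-DMSO	2.01	0.01
miRNA	mmu-miR-146a-5p	siOct4-DMSO_vs_siNT-DMSO	1.472	0.03
miRNA	mmu-miR-146b-5p	siOct4-DMSO_vs_siNT-DMSO	1.472	0.03
miRNA	mmu-miR-15b-5p	siOct4-DMSO_vs_siNT-DMSO	1.428	0.04
miRNA	mmu-miR-10a-5p	siOct4-POVPC_vs_siOct4-DMSO	1.79	0.003
miRNA	mmu-miR-10b-5p	siOct4-POVPC_vs_siOct4-DMSO	1.79	0.003
miRNA	mmu-miR-15a-5p	siOct4-POVPC_vs_siOct4-DMSO	1.63	0.03
miRNA	mmu-miR-15b-5p	siOct4-POVPC_vs_siOct4-DMSO	1.63	0.03
miRNA	mmu-miR-30a-5p	siOct4-POVPC_vs_siOct4-DMSO	1.53	0.006
miRNA	mmu-miR-376a-3p	siOct4-POVPC_vs_siOct4-DMSO	1.66	0.04
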