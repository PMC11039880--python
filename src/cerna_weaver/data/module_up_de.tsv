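molecule_class	feature_id	comparison	fold_change	p
lncRNA	ENSMUST00000140952	siNT-POVPC_vs_siNT-DMSO	3.68	0.03
lncRNA	ENSMUST00000131663	siOct4-DMSO_vs_siNT-DMSO	3.03	0.001
lncRNA	ENSMUST00000155531	siOct4-DMSO_vs_siNT-DMSO	3.22	0.01
lncRNA	ENSMUST00000140952	siOct4-POVPC_vs_siOct4-DMSO	2.59	0.04
miRNA	mmu-miR-10a	siNT-POVPC_vs_siNT-DMSO	0.67	0.001
miRNA	mmu-miR-196a-1	siNT-POVPC_vs_siNT-DMSO	0.01	0.001
miRNA	mmu-miR-486-5p	siOct4-DMSO_vs_siNT-DMSO	0.89	0.014
miRNA	mmu-miR-96	siOct4-DMSO_vs_siNT-DMSO	0.53	0.001
miRNA	mmu-miR-155	siOct4-DMSO_vs_siNT-DMSO	0.79	0.016
miRNA	mmu-miR-122	siOct4-DMSO_vs_siNT-DMSO	0.46	0.001
miRNA	mmu-miR-196a-1	siOct4-POVPC_vs_siOct4-DMSO	0.01	0.001
miRNA	mmu-miR-10a	siOct4-POVPC_vs_siOct4-DMSO	0.67	0.001
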