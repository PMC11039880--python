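kind	source_id	target_id	binding_sites	evidence
lnc_mir	ENSMUST00000140952	mmu-miR-10a	7	validated
lnc_mir	ENSMUST00000140952	mmu-miR-196a-1	4	validated
lnc_mir	ENSMUST00000131663	mmu-miR-486-5p	4	validated
lnc_mir	ENSMUST00000131663	mmu-miR-96	4	validated
lnc_mir	ENSMUST00000155531	mmu-miR-155	4	validated
lnc_mir	ENSMUST00000155531	mmu-miR-122	4	validated
mir_mrna	mmu-miR-10a|mmu-miR-196a-1	Hoxb6		validated
mir_mrna	mmu-miR-10a|mmu-miR-196a-1	Hoxb7		validated
mir_mrna	mmu-miR-10a|mmu-miR-196a-1	Hoxb4		validated
mir_mrna	mmu-miR-10a|mmu-miR-196a-1	Hoxb9		validated
mir_mrna	mmu-miR-10a|mmu-miR-196a-1	Hoxb5		validated
mir_mrna	mmu-miR-10a|mmu-miR-196a-1	Hoxb3		validated
mir_mrna	mmu-miR-486-5p|mmu-miR-96	Aff3		validated
mir_mrna	mmu-miR-486-5p|mmu-miR-96	Rev1		validated
mir_mrna	mmu-miR-486-5p|mmu-miR-96	Eif5b		validated
mir_mrna	mmu-miR-155|mmu-miR-122	Zfp652		validated
mir_mrna	mmu-miR-155|mmu-miR-122	Gngt2		validated
mir_mrna	mmu-miR-155|mmu-miR-122	Phospho1		validated
mir_mrna	mmu-miR-155|mmu-miR-122	Phb		validated
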