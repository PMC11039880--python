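kind	source_id	target_id	binding_sites	evidence
lnc_mir	ENSMUST00000151998	mmu-miR-15a-5p	22	validated
lnc_mir	ENSMUST00000151998	mmu-miR-322-5p	6	validated
lnc_mir	ENSMUST00000137236	mmu-miR-146a-5p	15	validated
lnc_mir	ENSMUST00000137236	mmu-miR-146b-5p	15	validated
lnc_mir	ENSMUST00000137236	mmu-miR-15b-5p	13	validated
lnc_mir	ENSMUST00000173605	mmu-miR-10a-5p	3	validated
lnc_mir	ENSMUST00000173605	mmu-miR-10b-5p	3	validated
lnc_mir	ENSMUST00000173605	mmu-miR-15a-5p	2	validated
lnc_mir	ENSMUST00000173605	mmu-miR-15b-5p	2	validated
lnc_mir	ENSMUST00000173605	mmu-miR-30a-5p	2	validated
lnc_mir	ENSMUST00000173605	mmu-miR-376a-3p	1	validated
mir_mrna	mmu-miR-15a-5p	Dedd		validated
mir_mrna	mmu-miR-15a-5p	E2f3		validated
mir_mrna	mmu-miR-15a-5p	Tmem178b		validated
mir_mrna	mmu-miR-15a-5p	Capza2		validated
mir_mrna	mmu-miR-15a-5p	Glud1		validated
mir_mrna	mmu-miR-15a-5p	Sema3a		validated
mir_mrna	mmu-miR-15a-5p	Cbfa2t3		validated
mir_mrna	mmu-miR-15a-5p	Nr2c2		validated
mir_mrna	mmu-miR-15a-5p	Ttc14		validated
mir_mrna	mmu-miR-15a-5p	Clock		validated
mir_mrna	mmu-miR-322-5p	Rnf111		validated
mir_mrna	mmu-miR-322-5p	Rgs8		validated
mir_mrna	mmu-miR-322-5p	Slc4a4		validated
mir_mrna	mmu-miR-322-5p	E2f3		validated
mir_mrna	mmu-miR-322-5p	Arpp21		validated
mir_mrna	mmu-miR-322-5p	Cyb561a3		validated
mir_mrna	mmu-miR-322-5p	Htr4		validated
mir_mrna	mmu-miR-322-5p	Lcor		validated
mir_mrna	mmu-miR-322-5p	Akap7		validated
mir_mrna	mmu-miR-322-5p	Slc22a23		validated
mir_mrna	mmu-miR-322-5p	Acvr2b		validated
mir_mrna	mmu-miR-322-5p	Adrb2		validated
mir_mrna	mmu-miR-146a-5p	Traf6		validated
mir_mrna	mmu-miR-146a-5p	Rsad2		validated
mir_mrna	mmu-miR-146b-5p	Kctd15		validated
mir_mrna	mmu-miR-146b-5p	Zfp532		validated
mir_mrna	mmu-miR-146b-5p	Strbp		validated
mir_mrna	mmu-miR-146b-5p	Ehf		validated
mir_mrna	mmu-miR-146b-5p	Gabrb1		validated
mir_mrna	mmu-miR-146b-5p	Smad4		validated
mir_mrna	mmu-miR-146b-5p	Angptl2		validated
mir_mrna	mmu-miR-146b-5p	Sfpq		validated
mir_mrna	mmu-miR-146b-5p	Primpol		validated
mir_mrna	mmu-miR-146b-5p	Tlcd5		validated
mir_mrna	mmu-miR-146b-5p	Btla		validated
mir_mrna	mmu-miR-146b-5p	Dcp1a		validated
mir_mrna	mmu-miR-146b-5p	Itm2b		validated
mir_mrna	mmu-miR-146b-5p	Syt1		validated
mir_mrna	mmu-miR-146b-5p	Traf6		validated
mir_mrna	mmu-miR-146b-5p	Ar		validated
mir_mrna	mmu-miR-146b-5p	Slamf1		validated
mir_mrna	mmu-miR-146b-5p	Lipa		validated
mir_mrna	mmu-miR-146b-5p	Znrf3		validated
mir_mrna	mmu-miR-146b-5p	Card10		validated
mir_mrna	mmu-miR-15b-5p	Tspyl2		validated
mir_mrna	mmu-miR-15b-5p	Gpr174		validated
mir_mrna	mmu-miR-15b-5p	Tmem178b		validated
mir_mrna	mmu-miR-15b-5p	Cyb561a3		validated
mir_mrna	mmu-miR-15b-5p	Atxn1l		validated
mir_mrna	mmu-miR-15b-5p	Clock		validated
mir_mrna	mmu-miR-15b-5p	Ncl		validated
mir_mrna	mmu-miR-15b-5p	Fgd4		validated
mir_mrna	mmu-miR-10a-5p	Mapre1		validated
mir_mrna	mmu-miR-10a-5p	Epha5		validated
mir_mrna	mmu-miR-10a-5p	Myt1l		validated
mir_mrna	mmu-miR-10a-5p	Tiam1		validated
mir_mrna	mmu-miR-10a-5p	Flt1		validated
mir_mrna	mmu-miR-10a-5p	Nr6a1		validated
mir_mrna	mmu-miR-10a-5p	Hoxa1		validated
mir_mrna	mmu-miR-10a-5p	Prrx1		validated
mir_mrna	mmu-miR-10a-5p	Xrn1		validated
mir_mrna	mmu-miR-10a-5p	Mapkbp1		validated
mir_mrna	mmu-miR-10a-5p	Hoxd10		validated
mir_mrna	mmu-miR-10a-5p	Nr4a3		validated
mir_mrna	mmu-miR-10a-5p	Rybp		validated
mir_mrna	mmu-miR-10a-5p	Lpar2		validated
mir_mrna	mmu-miR-10a-5p	Rhpn2		validated
mir_mrna	mmu-miR-10a-5p	Hdac4		validated
mir_mrna	mmu-miR-10b-5p	Hoxd10		validated
mir_mrna	mmu-miR-10b-5p	Iffo2		validated
mir_mrna	mmu-miR-10b-5p	Usp45		validated
mir_mrna	mmu-miR-10b-5p	Tiam1		validated
mir_mrna	mmu-miR-10b-5p	Hoxb3		validated
mir_mrna	mmu-miR-10b-5p	Tiam1		validated
mir_mrna	mmu-miR-30a-5p	Ccne2		validated
mir_mrna	mmu-miR-30a-5p	Gramd2		validated
mir_mrna	mmu-miR-30a-5p	Adam9		validated
mir_mrna	mmu-miR-30a-5p	Itga6		validated
mir_mrna	mmu-miR-30a-5p	Ppp3cb		validated
mir_mrna	mmu-miR-30a-5p	Sema3a		validated
mir_mrna	mmu-miR-376a-3p	Bcl9l		validated
mir_mrna	mmu-miR-376a-3p	Kmt2a		validated
mir_mrna	mmu-miR-376a-3p	Zfp148		validated
mir_mrna	mmu-miR-376a-3p	Cdc34		validated
mir_mrna	mmu-miR-376a-3p	E2f3		validated
mir_mrna	mmu-miR-376a-3p	Crygf		validated
mir_mrna	mmu-miR-376a-3p	Snx10		validated
mir_mrna	mmu-miR-376a-3p	Zdhhc23		validated
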