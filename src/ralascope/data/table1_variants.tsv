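proband_id	family_id	monozygotic_set_id	gene	transcript	cdna_change	protein_change	inheritance	site
Proband1	F1		RALA	NM_005402.3	c.73G>A	p.(V25M)	de novo	SiteA
Proband2	F2		RALA	NM_005402.3	c.73G>A	p.(V25M)	de novo	SiteB
Proband3	F3		RALA	NM_005402.3	c.73G>A	p.(V25M)	de novo	SiteC
Proband4	F4	MZ1	RALA	NM_005402.3	c.73G>T	p.(V25L)	de novo	SiteD
Proband5	F4	MZ1	RALA	NM_005402.3	c.73G>T	p.(V25L)	de novo	SiteD
Proband6	F5		RALA	NM_005402.3	c.383A>G	p.(K128R)	de novo	SiteE
Proband7	F6		RALA	NM_005402.3	c.383A>G	p.(K128R)	de novo	SiteF
Proband8	F7		RALA	NM_005402.3	c.389A>G	p.(D130G)	de novo	SiteF
Proband9	F8		RALA	NM_005402.3	c.469T>G	p.(S157A)	de novo	SiteF
Proband10	F9		RALA	NM_005402.3	c.472_474delGCT	p.(A158del)	de novo	SiteF
Proband11	F10		RALA	NM_005402.3	c.526C>T	p.(R176X)	unknown	SiteA
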