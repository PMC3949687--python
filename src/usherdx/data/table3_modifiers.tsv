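patient_id	biallelic_gene	modifier_gene	hgvs_c	hgvs_p	control_freq	sift	polyphen	reference	zygosity
5	MYO7A	CDH23	c.719C>T	p.Pro240Leu	0.26	0.06	0.999	Wagatsuma et al. (2007)	hom
8	MYO7A	CDH23	c.2568C>G	p.Ile856Met	0	0.08	1	This study	het
15	CDH23	USH1C	c.2437T>G	p.Tyr813Asp	0	0.19	0.932	This study	het
3	PCDH15	USH1G	c.28C>T	p.Arg10Trp	0	0.19	1	This study	het
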