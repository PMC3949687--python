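individual_id	gene	hgvs_c	genotype
4	MYO7A	c.2311G>T	het
4	PCDH15	c.158-1G>A	het
mother4	MYO7A	c.2311G>T	het
mother4	PCDH15	c.158-1G>A	ref
father4	MYO7A	c.2311G>T	ref
father4	PCDH15	c.158-1G>A	het
brother4a	MYO7A	c.2311G>T	het
brother4a	PCDH15	c.158-1G>A	ref
brother4b	MYO7A	c.2311G>T	ref
brother4b	PCDH15	c.158-1G>A	ref
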