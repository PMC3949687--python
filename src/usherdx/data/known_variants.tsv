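gene	hgvs_c	citation
MYO7A	c.1623dup	Le Quesne Stabej et al. (2012)
MYO7A	c.2311G>T	Nakanishi et al. (2010)
MYO7A	c.6028G>A	Jacobson et al. (2009)
CDH23	c.6319C>T	Nakanishi et al. (2010)
PCDH15	c.2971C>T	Roux et al. (2006)
CDH23	c.719C>T	Wagatsuma et al. (2007)
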