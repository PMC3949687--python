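gene	mutation_type	hgvs_c	hgvs_p	location	domain	control_freq	sift	polyphen	reference	flags
MYO7A	Frameshift	c.1623dup	p.Lys542GlnfsX5	Exon 14	-	N/A			Le Quesne Stabej et al. (2012)	homopolymer_region
MYO7A	Frameshift	c.4482_4483insTG	p.Trp1495CysfsX55	Exon 34	-	N/A			This study
MYO7A	Frameshift	c.6205_6206delAT	p.Ile2069ProfsX6	Exon 45	-	N/A			This study
MYO7A	Nonsense	c.1477C>T	p.Gln493X	Exon 13	-	N/A			This study
MYO7A	Nonsense	c.1708C>T	p.Arg570X	Exon 15	-	N/A			This study
MYO7A	Nonsense	c.2115C>A	p.Cys705X	Exon 18	-	N/A			This study
MYO7A	Nonsense	c.6321G>A	p.Trp2107X	Exon 46	-	N/A			This study
MYO7A	Missense	c.2074G>A	p.Val692Met	Exon 17	Motor domain	0	0.09	0.982	This study
MYO7A	Missense	c.2311G>T	p.Ala771Ser	Exon 20	IQ 2	0.0026	0.01	0.825	Nakanishi et al. (2010)
MYO7A	Missense	c.6028G>A	p.Asp2010Asn	Exon 44	FERM 2	0	0	0.925	Jacobson et al. (2009)
CDH23	Frameshift	c.3567delG	p.Arg1189ArgfsX5	Exon 30	-	N/A			This study
CDH23	Frameshift	c.5780_5781delCT	p.Ser1927Cysfs16	Exon 44	-	N/A			This study
CDH23	Splicing	c.5821-2A>G	?	Intron 44	-	N/A			This study	outside_design
CDH23	Nonsense	c.6319C>T	p.Arg2107X	Exon 48	-	N/A			Nakanishi et al. (2010)
PCDH15	Splicing	c.158-1G>A	?	Intron 3	-	N/A			This study
PCDH15	Nonsense	c.1006C>T	p.Arg336X	Exon 10	-	N/A			This study
PCDH15	Nonsense	c.2971C>T	p.Arg991X	Exon 22	-	N/A			Roux et al. (2006)
PCDH15	Nonsense	c.3337G>T	p.Glu1113X	Exon 25	-	N/A			This study
PCDH15	Missense	c.3724G>A	p.Val1242Met	Exon 28	Cadherin 11	0	0	1	This study
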