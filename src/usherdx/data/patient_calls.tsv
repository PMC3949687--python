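patient_id	gene	hgvs_c	hgvs_p	location	depth	mean_base_quality	alt_fraction	flags
1	MYO7A	c.1477C>T	p.Gln493X	Exon 13	314	30.0	0.50
1	MYO7A	c.4482_4483insTG	p.Trp1495CysfsX55	Exon 34	314	30.0	0.50
2	MYO7A	c.6205_6206delAT	p.Ile2069ProfsX6	Exon 45	314	30.0	0.99
5	MYO7A	c.2074G>A	p.Val692Met	Exon 17	314	30.0	0.99
5	CDH23	c.719C>T	p.Pro240Leu		314	30.0	0.99
6	MYO7A	c.1708C>T	p.Arg570X	Exon 15	314	30.0	0.99
8	MYO7A	c.1623dup	p.Lys542GlnfsX5	Exon 14	314	30.0	0.99	homopolymer_region
8	CDH23	c.2568C>G	p.Ile856Met		314	30.0	0.50
11	MYO7A	c.6028G>A	p.Asp2010Asn	Exon 44	314	30.0	0.50
11	MYO7A	c.6321G>A	p.Trp2107X	Exon 46	314	30.0	0.50
17	MYO7A	c.2115C>A	p.Cys705X	Exon 18	314	30.0	0.99
7	CDH23	c.3567delG	p.Arg1189ArgfsX5	Exon 30	314	30.0	0.99
9	CDH23	c.5780_5781delCT	p.Ser1927Cysfs16	Exon 44	314	30.0	0.50
9	CDH23	c.5821-2A>G	?	Intron 44	314	30.0	0.50	outside_design
15	CDH23	c.6319C>T	p.Arg2107X	Exon 48	314	30.0	0.99
15	USH1C	c.2437T>G	p.Tyr813Asp		314	30.0	0.50
3	PCDH15	c.3337G>T	p.Glu1113X	Exon 25	314	30.0	0.99
3	USH1G	c.28C>T	p.Arg10Trp		314	30.0	0.50
16	PCDH15	c.2971C>T	p.Arg991X	Exon 22	314	30.0	0.99
10	PCDH15	c.2884C>T	p.Arg962Cys		314	30.0	0.50
12	PCDH15	c.1006C>T	p.Arg336X	Exon 10	314	30.0	0.50
13	PCDH15	c.3724G>A	p.Val1242Met	Exon 28	314	30.0	0.50
4	MYO7A	c.2311G>T	p.Ala771Ser	Exon 20	314	30.0	0.50
4	PCDH15	c.158-1G>A	?	Intron 3	314	30.0	0.50
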