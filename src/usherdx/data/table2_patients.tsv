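patient_id	age	sex	gene_group	hereditary_form	onset_night_blindness	cataract	hearing_aid	cochlear_implant	pedigree_id
1	37	M	MYO7A	sporadic	13	no	unilateral	unilateral
2	41	F	MYO7A	AR	unknown	both eyes	bilateral	no
5	54	M	MYO7A	AR	5	both eyes	no	no
6	54	F	MYO7A	sporadic	6	no	no	no
8	14	M	MYO7A	sporadic	6	no	unilateral	unilateral
11	54	M	MYO7A	sporadic	13	no	no	no
17	56	F	MYO7A	sporadic	unknown	no	no	no
7	12	F	CDH23	sporadic	12	both eyes	no	bilateral
9	9	M	CDH23	sporadic	8	no	unilateral	unilateral
15	16	F	CDH23	sporadic	unknown	no	no	no
3	47	F	PCDH15	sporadic	5	both eyes	no	no
16	28	F	PCDH15	AR	10	no	no	no
10	62	M	PCDH15	sporadic	9	both eyes	no	no
12	52	M	PCDH15	sporadic	3	no	no	no
13	51	M	PCDH15	sporadic	10	no	no	no
4	21	M	MYO7A/PCDH15	sporadic	10	no	unilateral	unilateral	FAM4
14	64	F	unknown	sporadic	15	both eyes	unilateral	no
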