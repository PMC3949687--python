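FAM4	father4	0	0	1	1
FAM4	mother4	0	0	2	1
FAM4	4	father4	mother4	1	2
FAM4	brother4a	father4	mother4	1	1
FAM4	brother4b	father4	mother4	1	1
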