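name	recognition	cut_top	cut_bottom
XmaI	CCCGGG	1	5
NheI	GCTAGC	1	5
AvrII	CCTAGG	1	5
AfeI	AGCGCT	3	3
AscI	GGCGCGCC	2	6
PmeI	GTTTAAAC	4	4
BsrGI	TGTACA	1	5
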