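arm	clone	yield_mg_per_l	pct_monomer
OPAL-T	TF8	21	86
OPAL-T	TE6	32	65
OPAL-T	TD4	22	58
OPAL-T	TD3	32	70
OPAL-T	TC11	26	77
OPAL-S	SG10	12.4	75
OPAL-S	SF9	4.1	34
OPAL-S	SB10	5.8	79
OPAL-S	SD7	23.3	35
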