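antigen	arm	round	elisa_positive	screened	unique	sequenced
hNinj1	OPAL-T-k	3	91	94	2	5
hNinj1	OPAL-T-k	4	93	94
hNinj1	OPAL-T-l	3	52	94	4	6
hNinj1	OPAL-T-l	4	94	94	2	6
hNinj1	OPAL-S-k	3	66	94	1	4
hNinj1	OPAL-S-k	4
hNinj1	OPAL-S-l	3	4	94	3	7
hNinj1	OPAL-S-l	4	8	94	2	3
CARS	OPAL-T-k	3	91	94	3	8
CARS	OPAL-T-k	4	91	94	2	10
CARS	OPAL-T-l	3	91	94	7	8
CARS	OPAL-T-l	4	92	94	8	8
CARS	OPAL-S-k	3	46	94	10	12
CARS	OPAL-S-k	4	89	94	5	9
CARS	OPAL-S-l	3	91	94	5	10
CARS	OPAL-S-l	4	94	94	3	8
AgX	OPAL-T-k	3	48	94	4	8
AgX	OPAL-T-k	4	24	94	6	9
AgX	OPAL-T-l	3	19	94	10	13
AgX	OPAL-T-l	4	10	94	7	7
AgX	OPAL-S-k	3	16	94	11	13
AgX	OPAL-S-k	4	2	94	2	2
AgX	OPAL-S-l	3	5	94	3	3
AgX	OPAL-S-l	4	4	94	1	1
BCMA	OPAL-T-k	4
BCMA	OPAL-T-l	4	90	94	5	11
BCMA	OPAL-S-k	4	2	47	2	2
BCMA	OPAL-S-l	4	1	47	1	1
CD22	OPAL-T-k	4
CD22	OPAL-T-l	4	92	94	3	8
CD22	OPAL-S-k	4	12	94	2	6
CD22	OPAL-S-l	4	27	94	2	8
HEWL	OPAL-T-k	4	1	188	1	1
HEWL	OPAL-T-l	4	4	188	3	4
HEWL	OPAL-S-k	4	24	94	1	6
HEWL	OPAL-S-l	4	45	94	5	25
SARS	OPAL-T-l	4	80	94	4	5
SARS	OPAL-S-kl	4	16	94	3	14
AIMP1	OPAL-T-l	4	86	94	5	5
AIMP1	OPAL-S-kl	4	66	94	5	8
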