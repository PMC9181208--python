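h3_length	light_chain	size	dot_blot_pct	dot_blot_positive	dot_blot_assayed
9	kappa	3.7e8	31.8	7	22
10	kappa	6.2e8	54.5	12	22
11	kappa	4.8e8	54.5	12	22
12	kappa	5.0e8	31.8	7	22
13	kappa	2.2e8	18.2	4	22
14	kappa	4.1e8	54.5	12	22
15	kappa	3.5e8	45.5	10	22
16	kappa	5.1e8	36.4	8	22
9	lambda	0.9e9	54.5	12	22
10	lambda	1.5e9	45.5	10	22
11	lambda	1.4e9	45.5	10	22
12	lambda	1.4e9	50.0	11	22
13	lambda	1.1e9	50.0	11	22
14	lambda	1.0e9	59.1	13	22
15	lambda	1.4e9	50.0	11	22
16	lambda	1.9e9	54.5	12	22
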