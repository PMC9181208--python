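clone	k_on	k_off	k_d
CARS-B6	1.0e5	4.2e-3	4.1e-8
CARS-D7	1.6e4	2.2e-3	1.3e-7
CARS-D11	2.8e4	2.3e-3	8.2e-8
CARS-F4	3.6e4	3.7e-3	1.1e-7
BCMA-A3	8.7e4	2.6e-3	3.0e-8
BCMA-B5	7.5e4	2.7e-3	3.7e-8
BCMA-D11	2.4e4	1.9e-3	7.6e-8
AIMP1-C6	5.4e4	1.5e-3	2.8e-8
AIMP1-D4	3.2e4	2.5e-3	7.6e-8
AIMP1-E7	1.8e4	2.0e-3	1.1e-7
SARS-D6	5.8e4	1.1e-3	2.0e-8
SARS-F4	1.5e5	4.0e-3	2.7e-8
CD22-D1	1.4e4	6.2e-4	4.5e-8
HEWL-H5	5.0e3	1.8e-3	3.6e-7
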