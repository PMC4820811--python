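lane	condition	sample_id	total_reads	mapped_reads	mapped_wo_dup	properly_paired
1	control	CNT-A1	29.62	25.50	24.50	19.32
1	control	CNT-A2	34.17	29.52	28.62	22.94
1	control	CNT-A3	29.39	25.33	24.60	19.93
1	control	CNT-A4	30.13	26.08	25.50	20.71
1	mutant	MUT-A1	26.35	21.89	21.06	16.31
1	mutant	MUT-A2	24.93	20.78	20.30	16.30
1	mutant	MUT-A3	23.76	19.70	19.27	15.45
1	mutant	MUT-A4	29.95	25.01	24.43	19.58
1	wildtype	WT-A1	28.01	23.30	22.48	17.49
1	wildtype	WT-A2	29.25	24.91	24.27	19.64
1	wildtype	WT-A3	31.18	26.36	25.72	20.87
1	wildtype	WT-A4	31.35	26.52	25.81	20.94
2	control	CNT-B1	31.24	26.66	25.42	19.33
2	control	CNT-B2	27.57	23.58	22.95	17.86
2	control	CNT-B3	28.73	24.82	24.19	19.13
2	control	CNT-B4	28.91	24.90	24.24	19.10
2	mutant	MUT-B1	30.74	25.30	24.51	18.64
2	mutant	MUT-B2	30.13	25.02	24.62	19.34
2	mutant	MUT-B3	32.35	27.17	26.46	20.79
2	mutant	MUT-B4	31.89	26.74	26.14	20.59
2	wildtype	WT-B1	26.06	21.70	20.98	15.98
2	wildtype	WT-B2	34.50	29.08	28.43	22.51
2	wildtype	WT-B3	29.99	25.51	24.94	19.85
2	wildtype	WT-B4	32.18	27.25	26.69	21.37
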