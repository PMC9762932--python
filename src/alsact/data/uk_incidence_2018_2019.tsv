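age_group	sex	rate_per_100k	rate_lo	rate_hi	expected_sporadic_per_year	expected_lo	expected_hi
<40	male	0.080	0.022	0.20	7.03	1.92	18.01
<40	female	0.020	0.0005	0.011	1.78	0.045	9.91
40-49	male	0.89	0.54	1.38	35.74	21.83	55.19
40-49	female	0.40	0.18	0.75	16.24	7.43	30.83
50-59	male	2.67	1.98	3.53	89.11	65.92	117.81
50-59	female	0.80	0.45	1.32	27.35	15.31	45.12
60-69	male	3.19	2.38	4.20	93.03	69.27	122.32
60-69	female	2.91	2.15	3.85	89.05	65.88	117.73
>=70	male	3.65	2.75	4.73	99.90	75.46	129.73
>=70	female	3.20	2.48	4.08	118.52	91.66	150.79
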