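marker_id	chromosome	band_sizes	indica_band	japonica_band	indel_size	dominant	pic	rp	npa	ppa	emr	mi
R1M7	1	195,157	195	157	38	0	0.05	0.11	2	1	2	0.1
R1M30	1	248,202	248	202	46	0	0.38	1.24	2	1	2	0.76
R1M37	1	167		167	0	1	0.01	0.01	2	1	2	0.02
R1M47	1	162,110	162	110	52	0	0.2	0.47	2	1	2	0.4
R2M10	2	188,141	188	141	47	0	0.09	0.11	2	1	2	0.18
R2M24	2	167,136	167	136	31	0	0.21	0.49	2	1	2	0.42
R2M26	2	180,146	180	146	34	0	0.24	0.64	2	1	2	0.48
R2M37	2	211,151	211	151	60	0	0.42	1.85	2	1	2	0.85
R2M50	2	249,210	249	210	39	0	0.21	0.48	2	1	2	0.42
R3M10	3	194,171	194	171	23	0	0.03	0.06	2	1	2	0.06
R3M23	3	226,189	226	189	37	0	0.21	0.47	2	1	2	0.42
R3M30	3	186,163	186	163	23	0	0.08	0.17	2	1	2	0.16
R3M37	3	282,240,194	194	282	42	0	0.48	1.46	3	2	6	2.88
R3M53	3	209,175	209	175	34	0	0.44	1.46	2	1	2	0.89
R4M13	4	184,178	184	178	6	0	0.2	0.46	2	1	2	0.41
R4M17	4	227,175	227	175	52	0	0.44	1.85	2	1	2	0.89
R4M30	4	165,130	165	130	35	0	0.49	1.78	2	1	2	0.98
R4M43	4	208,171	208	171	37	0	0.23	0.54	2	1	2	0.47
R4M50	4	173,144	173	144	29	0	0.37	0.99	2	1	2	0.74
R5M13	5	213,178	213	178	35	0	0.23	0.52	2	1	2	0.45
R5M30	5	222,179	222	179	43	0	0.46	1.45	2	1	2	0.91
R6M14	6	256,221	256	221	35	0	0.43	1.29	2	1	2	0.85
R6M44	6	164,128	164	128	36	0	0.2	0.47	2	1	2	0.4
R7M7	7	213,145	213	145	68	0	0.36	0.96	2	1	2	0.73
R7M20	7	225,212	225	212	13	0	0.98	0.02	2	1	2	1.96
R7M37	7	182,164	182	164	18	0	0.03	0.07	2	1	2	0.06
R8M23	8	168,127	168	127	41	0	0.01	0.02	2	1	2	0.02
R8M33	8	213,175	213	175	38	0	0.44	1.39	2	1	2	0.88
R9M10	9	184,143	184	143	41	0	0.39	1.04	2	1	2	0.78
R9M20	9	187,137	187	137	50	0	0.22	0.48	2	1	2	0.44
R9M30	9	197,165	197	165	32	0	0.27	0.65	2	1	2	0.54
R9M42	9	231,218	231	218	13	0	0.03	0.06	2	1	2	0.06
R10M10	10	177,138	177	138	39	0	0.43	1.86	2	1	2	0.86
R10M17	10	158,128	158	128	30	0	0.07	0.15	2	1	2	0.14
R10M30	10	206,189	206	189	17	0	0.47	1.85	2	1	2	0.93
R10M40	10	164,134	164	134	30	0	0.01	0.02	2	1	2	0.02
R11M23	11	253,215	253	215	38	0	0.19	0.44	2	1	2	0.39
R11M40	11	185,141	185	141	44	0	0.38	1.18	2	1	2	0.76
R12M10	12	268,221	268	221	47	0	0.01	0.05	2	1	2	0.02
R12M27	12	185,156	185	156	29	0	0.35	0.9	2	1	2	0.7
R12M33	12	264,219	264	219	45	0	0.5	1.8	2	1	2	1
R12M43	12	204,174	204	174	30	0	0.2	0.45	2	1	2	0.4
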