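age_weeks	syllable	control_velocity	control_velocity_sem	lesion_velocity	lesion_velocity_sem	velocity_p	control_usage	control_usage_sem	lesion_usage	lesion_usage_sem	usage_p
8	0	66.6	3.6	67.13	2.85	0.562	0.2318	0.0068	0.2356	0.0058	0.689
8	1	99.41	2.19	104.32	2.83	0.252	0.1511	0.0053	0.156	0.0061	0.598
8	2	91.58	2.75	94.08	4.11	0.810	0.118	0.004	0.1225	0.0052	0.887
8	3	72.25	1.63	70.1	2.02	0.350	0.1003	0.0055	0.1087	0.0051	0.272
8	4	46.13	1.19	51.08	3.7	0.802	0.0573	0.0085	0.0469	0.0072	0.397
8	5	141.97	5.93	142.68	6.63	0.985	0.0545	0.0035	0.057	0.0036	0.749
8	6	111.32	3.96	110.33	3.79	0.957	0.0332	0.0028	0.0365	0.0021	0.423
8	7	69.33	3.14	68.27	2.6	0.933	0.024	0.0018	0.025	0.0026	0.940
8	8	96.51	3.33	103.27	3.19	0.450	0.0319	0.0042	0.0231	0.0029	0.266
8	9	37.06	1.55	39.28	1.31	0.334	0.0142	0.0011	0.0136	0.0013	0.569
8	10	88.38	4.46	85.84	5.8	0.911	0.0251	0.0027	0.0239	0.0031	0.716
8	11	86.55	2.91	85.82	2.4	0.922	0.0272	0.0014	0.0254	0.0016	0.490
8	12	103.02	5.65	113.15	12.81	0.966	0.0145	0.0025	0.0132	0.0025	0.754
8	13	115.45	4.84	119.6	10.68	0.847	0.0172	0.0015	0.0159	0.0019	0.705
8	14	158.66	7.2	160.87	9.88	0.741	0.0146	0.0011	0.0129	0.0013	0.454
8	15	100.51	5.65	98.25	4.27	0.937	0.0131	0.0016	0.0141	0.0017	0.585
8	16	139.45	4.76	141.85	5.59	0.553	0.008	0.0008	0.0102	0.0006	0.036
8	17	58.56	2.61	60.93	2.62	0.722	0.0098	0.0011	0.0079	0.0006	0.465
8	18	33.33	0.79	37.11	1.8	0.270	0.0042	0.0005	0.0041	0.0006	0.911
8	19	81.24	6.11	108.62	18.42	0.388	0.0053	0.0013	0.0042	0.0011	0.578
8	20	192	9.74	195.98	6.46	0.593	0.0058	0.0007	0.0069	0.0005	0.348
8	21	168.65	6.95	159.22	5.18	0.444	0.006	0.0006	0.0059	0.0007	0.978
14	0	68.33	2.68	53.31	2.08	0.002	0.2446	0.0087	0.2509	0.0143	0.689
14	4	46.21	2.12	43.19	1.1	0.347	0.0326	0.0062	0.0606	0.0184	0.263
14	5	139.95	5.01	108.1	4.39	0.001	0.0612	0.0037	0.0595	0.0054	0.815
14	6	114.91	4.57	96.74	4.24	0.018	0.0406	0.004	0.0293	0.0021	0.057
14	7	74.87	2.09	65.07	1.74	0.002	0.0245	0.0037	0.0343	0.0035	0.116
14	8	108.52	5.52	98.25	4.29	0.450	0.0161	0.0028	0.0329	0.013	0.403
14	9	40.67	2.33	36.84	1.87	0.387	0.0119	0.0015	0.0292	0.0043	0.012
14	10	85.59	7.98	82.49	5.96	0.911	0.0201	0.0042	0.0171	0.0033	0.771
14	11	99.78	3.61	74.89	6.17	0.022	0.0207	0.0026	0.0228	0.0039	0.872
14	12	82.52	7.59	89.96	9.43	0.521	0.0084	0.002	0.017	0.0042	0.203
14	13	120.52	7.7	98.55	6.49	0.129	0.0132	0.001	0.0159	0.0027	0.488
14	14	161.75	6.76	134.97	6.22	0.033	0.0182	0.0011	0.0128	0.0022	0.099
14	15	88.71	3.88	93.5	9.58	0.688	0.0165	0.0027	0.0083	0.0019	0.055
14	16	144.26	6.8	108.64	11.78	0.011	0.0099	0.0012	0.0055	0.0011	0.027
14	17	64.43	2.75	57.19	4.41	0.518	0.0059	0.0006	0.004	0.0006	0.053
14	18	34.35	1.53	32.75	0.56	0.584	0.0042	0.0007	0.0077	0.0023	0.442
14	19	79.26	8.18	69.42	4.39	0.391	0.0027	0.0006	0.0064	0.0017	0.430
14	20	182.02	8.75	161.35	7.37	0.118	0.0075	0.001	0.0045	0.0008	0.095
14	21	162.05	5.87	129.85	6.72	0.014	0.0061	0.001	0.0041	0.0005	0.193
24	0	62.43	1.74	51.5	1.6	0.003	0.218	0.0059	0.2099	0.0102	0.952
24	1	90.68	1.72	68.01	2.66	0.000	0.1163	0.0045	0.0653	0.0055	0.000
24	2	81.18	2.36	59.37	1.29	0.000	0.123	0.0042	0.1191	0.0057	0.887
24	3	68.23	1.77	56.73	1.92	0.007	0.1205	0.011	0.0535	0.0047	0.000
24	4	43.84	1.62	38.26	0.67	0.006	0.0732	0.0068	0.0891	0.0171	0.949
24	5	124.62	3.47	86.84	4.09	0.001	0.0559	0.0022	0.0679	0.0058	0.749
24	6	100.58	3.15	74.18	4.56	0.000	0.0296	0.0029	0.0079	0.0011	0.000
24	7	70.43	2.6	54.04	1.35	0.001	0.0273	0.0022	0.0721	0.0061	0.001
24	8	110.59	2.94	106.09	5.65	0.556	0.0326	0.0036	0.0369	0.0057	0.912
24	9	37.87	2.06	33.8	0.95	0.288	0.0163	0.0029	0.1098	0.0084	0.000
24	10	85.38	3.55	66.79	5.32	0.126	0.0274	0.0019	0.0149	0.0019	0.008
24	11	95.39	4.58	72.85	4.21	0.022	0.0146	0.0019	0.0185	0.0042	0.490
24	12	94.57	7.24	81.32	8.48	0.521	0.0246	0.0033	0.0285	0.007	0.754
24	13	104.17	6.23	73.9	2.74	0.003	0.0215	0.0017	0.0136	0.0014	0.019
24	14	149.61	3.86	102.39	10.84	0.002	0.018	0.0029	0.0062	0.0011	0.003
24	15	85.19	6.22	59.95	10.19	0.122	0.0101	0.001	0.002	0.0003	0.000
24	16	123.58	11.75	91.88	18.16	0.023	0.0032	0.0005	0.0024	0.0008	0.027
24	17	63.52	2.14	53.23	5.06	0.518	0.0082	0.0011	0.0022	0.0003	0.001
24	18	33.69	1.15	31.09	0.26	0.087	0.0061	0.0007	0.022	0.0026	0.000
24	19	76.17	4.67	67.89	3.1	0.207	0.0105	0.0017	0.013	0.0043	0.470
24	20	153.65	8.22	109.36	7.13	0.000	0.0046	0.0006	0.0022	0.0005	0.007
24	21	166.97	8.01	104.53	12.14	0.001	0.0042	0.0004	0.0028	0.0006	0.193
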