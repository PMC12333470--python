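syllable	control_velocity	control_velocity_sem	lesion_velocity	lesion_velocity_sem	treated_velocity	treated_velocity_sem	velocity_p_lesion_vs_control	velocity_p_lesion_vs_treated	control_usage	control_usage_sem	lesion_usage	lesion_usage_sem	treated_usage	treated_usage_sem	usage_p_lesion_vs_control	usage_p_lesion_vs_treated
0	53.38	8.07	29.35	0.95	53.28	8.2	0.002	0.048	0.0652	0.0104	0.2563	0.0271	0.1857	0.0415	0.001	0.090
1	103.24	12.6	49.03	2.67	94.37	12.87	0.000	0.009	0.1395	0.0162	0.0545	0.0106	0.0587	0.0115	0.001	0.905
2	50.44	7.42	29.46	1.33	43.56	6.31	0.002	0.123	0.1266	0.0173	0.0458	0.0072	0.0518	0.0095	0.001	0.634
3	21.01	3.07	15.99	1.05	25.73	5.26	0.127	0.127	0.063	0.0107	0.126	0.0097	0.0928	0.0215	0.001	0.249
4	76.36	8.34	37.83	1.33	53.69	6.88	0.001	0.044	0.0865	0.0117	0.028	0.0068	0.0324	0.0049	0.001	0.425
5	68.1	6.7	42.76	1.98	58.61	9.1	0.001	0.264	0.0915	0.0128	0.0475	0.0089	0.0271	0.0057	0.027	0.076
6	32.84	6.73	21.08	1.3	33.91	6.09	0.037	0.387	0.077	0.0111	0.0615	0.0094	0.0273	0.0048	0.500	0.012
7	38.86	3.22	26.97	1.27	36.08	5.57	0.003	0.538	0.0688	0.0102	0.0379	0.0056	0.0167	0.0025	0.050	0.008
8	41.79	4.15	25.99	1.65	61.41	10.65	0.006	0.006	0.0197	0.0035	0.1221	0.0142	0.0828	0.0205	0.001	0.108
9	74.37	6.7	45.36	2.94	79.33	14.25	0.001	0.060	0.0537	0.0097	0.0089	0.0021	0.0183	0.0062	0.001	0.175
10	96.31	13.74	42.77	3.71	75.38	11.99	0.002	0.027	0.0261	0.0021	0.0214	0.0024	0.0399	0.0143	0.551	0.848
11	76.21	10.69	57.18	12.68	155.71	11.28	0.156	0.156	0.0352	0.0209	0.0037	0.0012	0.009	0.0026	0.461	0.687
12	40.65	8.75	19.44	1.62	28.4	5.4	0.108	0.639	0.0136	0.003	0.027	0.0114	0.01	0.0049	0.809	0.387
13	95.74	14.3	83.94	46.85	176.32	12.94	0.816	0.816	0.0297	0.0175	0.0015	0.0003	0.0068	0.0018	0.761	0.761
14	116.94	15.97	66.52	6.29	104.61	16.63	0.019	0.114	0.0078	0.0025	0.0037	0.0014	0.0357	0.0169	0.145	0.027
15	97.67	24.44	44.26	2.92	85.52	12.52	0.509	0.121	0.0024	0.0006	0.027	0.0059	0.0386	0.0057	0.000	0.226
16	95.58	10.71	58.83	7	118	33.41	0.225	0.645	0.0115	0.003	0.0209	0.0104	0.0128	0.0043	0.950	0.950
17	68.17	12.39	54.62	20.75	159.99	11.53	0.317	0.317	0.0164	0.0119	0.0037	0.0013	0.0042	0.0012	0.782	0.782
18	14.6	2.69	13.44	1.37	29	8.25	0.345	0.015	0.0017	0.0003	0.0428	0.0098	0.0197	0.0076	0.000	0.033
19	96.12	13.66	44.64	7.58	75.94	13.42	0.004	0.149	0.0033	0.0008	0.0102	0.0052	0.0314	0.0146	0.654	0.400
20	45.88	6.2	38.8	5.66	49.25	13.06	0.248	0.248	0.0089	0.002	0.0131	0.006	0.0054	0.0042	0.453	0.066
21	98.89	5.93	76.72	20.04	98.58	55.07	0.557	0.607	0.0211	0.0096	0.0044	0.0016	0.0031	0.0019	0.452	0.452
22	125.46	32.82	64.66	19.2	121.67	19.58	0.245	0.029	0.0011	0.0002	0.0016	0.0007	0.0424	0.0219	0.808	0.020
23	103.42	28.76	71.26	0	133.12	14.79	0.314	0.058	0.0006	0.0001	0.0012	0	0.068	0.0347	0.456	0.058
24	105.26	50.25	50.54	0	130.72	13.56	0.123	0.005	0.0005	0.0001	0.0013	0	0.0482	0.0254	0.290	0.008
25	58.25	9.37	44.98	8.73	98.55	34.87	0.238	0.895	0.0056	0.0017	0.0145	0.0074	0.0068	0.0053	0.711	0.603
26	214.76	15.6	61.14	9.73	154.32	37.11	0.673	0.673	0.0018	0.0007	0.0017	0.0004	0.0627	0.0404	0.394	0.768
28	114.79	20.4	59.91	9.54	132.63	31.71	0.000	0.000	0.0006	0.0001	0.0016	0.0001	0.0581	0.0392	0.000	0.000
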