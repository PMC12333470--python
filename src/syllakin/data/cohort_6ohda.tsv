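syllable	control_velocity	control_velocity_sem	lesion_velocity	lesion_velocity_sem	velocity_p	control_usage	control_usage_sem	lesion_usage	lesion_usage_sem	usage_p
0	85.7	6.14	60.3	1.59	0.002	0.2139	0.004	0.2201	0.0127	0.291
1	99.5	4.41	71.7	2.76	0.000	0.1379	0.0045	0.113	0.006	0.008
2	89.1	3.81	63.2	1.45	0.000	0.1226	0.0038	0.103	0.017	0.236
3	75.7	3.5	61.9	1.44	0.000	0.1116	0.0065	0.0529	0.0078	0.000
4	35.8	0.33	33.4	0.4	0.002	0.0737	0.007	0.1144	0.0127	0.004
5	155.7	7.49	92	5.3	0.000	0.054	0.0038	0.0386	0.0046	0.020
6	105.4	4.77	74.9	4.58	0.001	0.0272	0.0024	0.0098	0.0023	0.001
7	72	2.82	60.3	2.57	0.019	0.0242	0.0033	0.0388	0.0073	0.369
8	103.9	5.41	91.3	7.26	0.158	0.0178	0.0013	0.0169	0.0049	0.156
9	43.5	3.33	50.9	2.86	0.120	0.0193	0.0037	0.0638	0.0064	0.000
10	74.6	3.76	69.8	4.21	0.360	0.0332	0.0024	0.0313	0.0041	0.528
11	109.3	5.87	77	2.85	0.000	0.0203	0.0027	0.0283	0.0029	0.052
12	83	4.3	80.7	5.19	0.624	0.0141	0.0018	0.0171	0.0076	0.330
13	91.7	10.79	65.2	3.28	0.034	0.0165	0.0012	0.0147	0.0013	0.333
14	172.43	3.58	91.67	5.96	0.000	0.0134	0.0018	0.0033	0.0008	0.000
15	96.3	4.2	74.1	8.05	0.023	0.0116	0.0014	0.0018	0.0007	0.000
17	69.3	2.18	55.6	4.88	0.017	0.0091	0.0046	0.0026	0.001	0.020
18	31.9	0.45	31.4	0.19	0.533	0.0416	0.0065	0.0912	0.0084	0.002
19	75	11.26	57.6	7.21	0.227	0.0053	0.0012	0.0088	0.0044	0.833
24	37.3	1.46	39.6	2.15	0.725	0.0033	0.0003	0.0064	0.0026	0.292
30	32.2	0.64	34.5	1.04	0.088	0.0022	0.0007	0.0081	0.0031	0.041
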