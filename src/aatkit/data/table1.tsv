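pair	ka	ks	ratio	date_my
GmCAT1-GmCAT2	0.011	0.103	0.110	8.43
GmCAT3-GmCAT4	0.063	0.121	0.518	9.96
GmCAT7-GmCAT9	0.163	0.933	0.174	76.51
GmCAT18-GmCAT19	0.058	0.171	0.338	13.98
GmPHS1-GmPHS2	0.061	0.348	0.176	28.53
GmPHS3-GmPHS4	0.037	0.114	0.326	9.32
GmACT2-GmACT3	0.007	0.121	0.061	9.95
GmACT4-GmACT6	0.088	0.400	0.220	32.81
GmATL1-GmATL2	0.010	0.102	0.099	8.38
GmATL11-GmATL12	0.244	0.228	1.070	18.65
ANT5-ANT6	0.033	0.109	0.304	8.91
ATL20-ATL21	0.101	0.201	0.504	16.49
ATL22-ATL23	0.098	0.165	0.596	13.53
ATL25-ATL26	0.269	0.177	1.523	14.50
ATL43-ATL44	0.017	0.121	0.139	9.94
AUX5-AUX6	0.009	0.083	0.105	6.78
AAP13-AAP14	0.008	0.086	0.098	7.02
AAP28-AAP29	0.006	0.129	0.050	10.56
GAT14-GAT15	0.007	0.102	0.066	8.39
ProT2-ProT3	0.033	0.180	0.186	14.74
LHT5-LHT6	0.004	0.116	0.037	9.54
LHT7-LHT8	0.098	0.202	0.487	16.55
LHT14-LHT15	0.114	0.243	0.470	19.92
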