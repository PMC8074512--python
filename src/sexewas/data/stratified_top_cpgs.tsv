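cpg	significant_in	estimate_female	se_female	p_female	estimate_male	se_male	p_male
cg09502865	female	0.179	0.028	2.50e-10	0.094	0.034	4.46e-01
cg05235171	female	-0.168	0.029	7.61e-09	-0.025	0.033	4.47e-01
cg15610437	female	-0.155	0.029	5.45e-08	-0.090	0.034	9.79e-02
cg13572782	female	0.157	0.029	5.75e-08	0.047	0.036	1.90e-01
cg17881200	female	0.152	0.029	1.41e-07	0.131	0.034	6.22e-02
cg22632947	female	-0.139	0.026	1.50e-07	-0.005	0.028	8.57e-01
cg15467503	female	-0.146	0.028	1.81e-07	-0.083	0.034	1.33e-01
cg26033526	female	0.148	0.029	2.64e-07	-0.021	0.034	5.23e-01
cg08363067	female	-0.120	0.024	7.68e-07	-0.050	0.028	7.41e-02
cg12926693	female	-0.149	0.030	8.59e-07	-0.067	0.035	5.19e-02
cg07687398	male	0.052	0.030	8.63e-02	0.183	0.035	1.16e-07
cg10513118	male	0.038	0.030	2.01e-01	0.172	0.033	1.42e-07
cg21253952	male	-0.019	0.030	5.33e-01	0.169	0.034	4.44e-07
cg18281939	male	-0.022	0.029	4.55e-01	-0.179	0.036	6.26e-07
cg11809272	male	-0.001	0.031	9.77e-01	0.161	0.033	9.08e-07
cg15952933	male	-0.058	0.033	7.56e-02	-0.156	0.032	9.48e-07
cg11614451	male	-0.041	0.029	1.56e-01	-0.150	0.031	1.28e-06
cg18942110	male	0.031	0.030	3.06e-01	-0.164	0.035	2.23e-06
cg01655008	male	-0.042	0.029	1.51e-01	-0.152	0.032	2.54e-06
cg02331272	male	0.058	0.030	1.10e-01	-0.166	0.036	2.99e-06
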