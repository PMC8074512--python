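cpg	estimate_female	se_female	p_female	estimate_male	se_male	p_male	estimate_interaction	se_interaction	p_interaction	adj_p_interaction
cg13212831	0.083	0.030	6.15e-03	-0.139	0.034	4.10e-05	-0.222	0.044	6.38e-07	3.54e-04
cg25734825	0.059	0.030	5.01e-02	-0.156	0.036	1.21e-05	-0.220	0.045	1.12e-06	6.22e-04
cg02331272	0.058	0.030	1.10e-01	-0.166	0.036	2.99e-06	-0.215	0.046	2.25e-06	1.25e-03
cg10622825	-0.069	0.030	2.22e-02	0.134	0.034	7.78e-05	0.200	0.045	7.00e-06	3.88e-03
cg10784067	-0.127	0.032	5.33e-05	0.068	0.033	3.78e-02	0.201	0.045	9.03e-06	5.01e-03
cg14284055	0.115	0.029	8.28e-05	-0.066	0.037	7.12e-02	-0.193	0.045	1.94e-05	1.07e-02
cg18942110	0.031	0.030	3.06e-01	-0.164	0.035	2.23e-06	-0.187	0.045	3.13e-05	1.74e-02
cg09342330	0.045	0.030	1.31e-01	-0.144	0.037	8.30e-05	-0.189	0.046	3.47e-05	1.93e-02
cg21722170	0.034	0.030	2.53e-01	-0.148	0.034	1.57e-05	-0.183	0.045	4.17e-05	2.31e-02
cg03662217	0.039	0.029	1.85e-01	-0.141	0.036	7.27e-05	-0.184	0.045	4.59e-05	2.55e-02
cg15026265	-0.038	0.029	1.95e-01	0.134	0.033	6.58e-05	0.176	0.044	6.72e-05	3.73e-02
cg00659421	-0.050	0.031	1.08e-01	0.130	0.033	7.53e-05	0.178	0.045	6.95e-05	3.86e-02
cg24917065	-0.135	0.030	6.26e-06	0.042	0.033	2.05e-01	0.174	0.044	6.98e-05	3.87e-02
cg18281939	-0.022	0.029	4.55e-01	-0.179	0.036	6.26e-07	-0.177	0.045	7.10e-05	3.94e-02
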