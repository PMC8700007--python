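species	comparison	point	lo	hi
p-S6K	KO/Baseline	25.57	5.44	120.68
p-S6	KO/Baseline	79.57	38.72	163.80
p-4EBP1	KO/Baseline	23.06	7.57	72.04
SMMHC	KO/Baseline	0.6474	0.3056	1.3622
SMA	KO/Baseline	0.7462	0.6376	0.8733
SM22	KO/Baseline	0.7440	0.6242	0.8918
p-AKT	KO/Baseline	0.4022	0.3395	0.4770
Col3a1	KO/Baseline	0.6195	0.4065	0.9443
Eln	KO/Baseline	0.4584	0.2623	0.8053
MMP2	KO/Baseline	1.6707	1.0885	2.5543
beta-catenin	KO/Baseline	1.7620	1.4623	2.1244
LAMP1	KO/Baseline	2.7029	1.5385	4.7815
LAMP2	KO/Baseline	3.6597	0.8488	15.7193
MITF	KO/Baseline	25.7681	12.8522	51.6854
SMMHC	Rapa/KO	1.9114	1.3746	2.6245
SMA	Rapa/KO	1.9259	1.3038	2.8642
SM22	Rapa/KO	2.3107	1.4538	3.6662
beta-catenin	Rapa/KO	0.6194	0.4687	0.8109
LAMP1	Rapa/KO	0.1931	0.1432	0.2613
LAMP2	Rapa/KO	0.0312	0.0012	0.8134
MITF	Rapa/KO	0.0	0.0	0.0
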