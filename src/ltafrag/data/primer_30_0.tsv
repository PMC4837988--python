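observed_mz	reported_mz	cleavage	description	flags
78.9589	78.9585	g & i	P - H3O
152.9959	152.9953	h	P-Gro - H3O
171.0062	171.0059	g	P-Gro - H
241.2171	241.2169	b1 or b2	(15:0) FA - H
315.0463	315.0481	f	Glc-P-Gro - H3O
477.1002	477.1010	d	Glc2-P-Gro - H3O
701.3100	701.3051	b1 & j	(15:0) MAG-Glc2-P - H3O	reported_mz_inconsistent
719.3195	719.3257	a1 & j	(15:0) MAG-Glc2-P - H
775.3502	775.3519	b1	(15:0) lyso-form - H3O
793.3617	793.3625	a1	(15:0) lyso-form - H
943.5303	943.5399	j	DAG-Glc2-P - H
1017.5769	1017.5770	[M-H]-	(30:0) LTAP - H
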