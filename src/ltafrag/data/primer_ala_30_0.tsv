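observed_mz	reported_mz	cleavage	description	flags
78.9587	78.9585	g & i	P - H3O
88.0405	88.0399	k	Ala - H
152.9959	152.9953	g & k	P-Gro - H3O
171.0062	171.0059	g & l	P-Gro - H
224.0316	224.0324	h	P-Gro-Ala - H3O
241.2170	241.2169	b1 or b2	(15:0) FA - H
459.0897	459.0904	d & k	Glc2-P-Gro - H2O - H3O
533.1236	533.1272	b1 & b2 & l	dilyso-LTAP - H2O - H3O
701.4	701.3051	b1 & j	(15:0) MAG-Glc2-P - H3O	qtrap_only;reported_mz_inconsistent
719.3294	719.3257	a1 & j	(15:0) MAG-Glc2-P - H
757.3343	757.3414	b1 & k	(15:0) lyso-LTAP - H2O - H3O
775.3481	775.3519	b1 & l	(15:0) lyso-LTAP - H3O
925.5254	925.5293	i	(30:0) DAG-Glc2-P - H3O
943.5386	943.5399	j	(30:0) DAG-Glc2-P - H
999.5662	999.5661	k	(30:0) LTAP - H3O
1088.6146	1088.6140	[M-H]-	(30:0) LTAP-Ala - H
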