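observed_mz	reported_mz	cleavage	description	flags
88.0401	88.0399	k or m	Ala - H
152.9946	152.9953	g & k & n	P-Gro - H3O
159.0762	159.0770	rearrangement	Ala-Ala - H
223.1704	223.1698		(14:2) FA - H	contaminant
241.2166	241.2169	b1 or b2	(15:0) FA - H
846.4	846.3891	b1 & l	(15:0) MAG-Glc2-P-Gro-Ala - H3O	qtrap_only
925.5	925.5293	i	(30:0) DAG-Glc2-P - H3O	qtrap_only
943.5	943.5399	j	(30:0) DAG-Glc2-P - H	qtrap_only
981.6	981.5550	k & m	(30:0) LTAP - H5O2	qtrap_only
999.5	999.5661	k & n	(30:0) LTAP - H3O	qtrap_only
1017.5774	1017.5770	l & n	(30:0) LTAP - H
1070.6092	1070.6030	k or m	(30:0) LTAP-Ala - H3O
1115.7	1115.6610	rearrangement	(30:0) LTAP-Ala2 - CO2 - H	qtrap_only
1159.6527	1159.6510	[M-H]-	(30:0) LTAP-Ala2 - H
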