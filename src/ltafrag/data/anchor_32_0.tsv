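observed_mz	reported_mz	cleavage	description	flags
299.2568	299.2588	a1 & c	(15:0) MAG - OH
327.2885	327.2901	a2 & c	(17:0) MAG - OH
347.0944	347.0955	d	Glc-Glc - H2O + Na+
365.1056	365.1060	c	Glc-Glc + Na+
405.1360	405.1374	b1 & b2	CH2=CH-CH2-Glc-Glc + Na+
483.2907	483.2936	b1 & f	(15:0) MAG-Glc - H2O + Na+
511.3233	511.3249	b2 & f	(17:0) MAG-Glc - H2O + Na+
645.3448	645.3464	b1	(15:0) MAG-Glc-Glc - H2O + Na+
673.3760	673.3777	b2	(17:0) MAG-Glc-Glc - H2O + Na+
753.5487	753.5496	f	(32:0) DAG-Glc + Na+
915.6005	915.6025	[M+Na]+	(32:0) DAG-Glc-Glc + Na+
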