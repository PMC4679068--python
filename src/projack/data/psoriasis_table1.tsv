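chrom	snp	pos_mb	gene	z	p	or_naive	or_repl
6	rs12191877	31.36	HLA-B	15.34	3.9e-53	2.79	2.64
5	rs2082412	158.65	UBLCP1	6.20	5.5e-10	1.56	1.44
5	rs17728338	150.46	ANXA6	5.20	2.0e-07	1.72	1.59
5	rs20541	132.02	IL13	4.53	5.8e-06	1.37	1.27
6	rs610604	138.24	TNFAIP3	4.34	1.4e-05	1.28	1.19
12	rs2066807	55.02	STAT2	4.33	1.5e-05	1.68	1.34
1	rs2201841	67.47	IL23R	5.13	2.9e-07	1.35	1.13
9	rs1076160	134.8	TSC1	4.24	2.2e-05	1.26	1.09
19	rs12983316	10.98	SMARCA4	4.23	2.3e-05	1.37	1.09
2	rs397211	113.6	IL1RN	3.29	1.0e-03	1.21	1.08
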