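rsid	gene	effect_allele	other_allele	eaf	beta	se
rs1471633	PDZK1	A	C	0.46	0.037	0.0033
rs1260326	GCKR	T	C	0.41	0.045	0.0032
rs12498742	SLC2A9	A	G	0.77	0.236	0.0034
rs2231142	ABCG2	T	G	0.11	0.124	0.0051
rs675209	RREB1	T	C	0.27	0.036	0.0039
rs1165151	SLC17A1	T	G	0.47	-0.051	0.0028
rs1171614	SLC16A9	T	C	0.22	-0.052	0.0046
rs2078267	SLC22A11	T	C	0.51	-0.048	0.0038
rs478607	NRXN2	A	G	0.84	-0.017	0.0037
rs3741414	INHBC	T	C	0.24	-0.043	0.0045
rs11264341	TRIM46	T	C	0.43	-0.033	0.0039
rs17050272	INHBB	A	G	0.43	0.023	0.0039
rs6770152	SFMBT1	T	G	0.58	-0.029	0.0033
rs17632159	TMEM171	C	G	0.31	-0.026	0.0039
rs729761	VEGFA	T	G	0.3	-0.031	0.0039
rs1178977	BAZ1B	A	G	0.81	0.031	0.0046
rs10480300	PRKAG2	T	C	0.28	0.023	0.0039
rs2941484	HNF4G	T	C	0.44	0.029	0.0033
rs10821905	A1CF	A	G	0.18	0.037	0.0046
rs642803	OVOL1	T	C	0.46	-0.024	0.0033
rs653178	ATXN2	T	C	0.51	-0.023	0.0033
rs1394125	UBE2Q2	A	G	0.34	0.028	0.0039
rs6598541	IGF1R	A	G	0.36	0.028	0.0039
rs7193778	NFAT5	T	C	0.86	-0.030	0.0052
rs7188445	MAF	A	G	0.33	-0.021	0.0033
rs7224610	HLF	A	C	0.58	-0.028	0.0033
rs742132	LRRC16A	A	G	0.7	0.035	0.0060
rs2307394	ORC4L	T	C	0.68	-0.019	0.0033
rs17786744	STC1	A	G	0.58	-0.019	0.0033
rs2079742	BCAS3	T	C	0.85	0.028	0.0052
rs164009	QRICH2	A	G	0.61	0.018	0.0033
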