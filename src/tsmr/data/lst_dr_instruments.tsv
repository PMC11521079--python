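rsid	effect_allele	other_allele	nearest_gene	beta_exp	se_exp	pval_exp	beta_out	se_out	pval_out	n_exp	f_stat
rs10189857	A	G	BCL11A	-0.027	0.004	7.8E-15	-0.012	0.014	.389	468924	252.33
rs10400776	A	C	VRK1	-0.026	0.004	3.45E-09	-0.025	0.017	.149	442658	182.69
rs10772643	T	C	EMP1	-0.039	0.006	5.88E-10	0.006	0.019	.770	468924	206.34
rs10889193	C	A	LINC01748	-0.024	0.004	4.94E-10	-0.007	0.015	.642	525479	200.33
rs11074658	T	C	GRIN2A	-0.024	0.004	9.21E-10	0.004	0.015	.799	442658	196.06
rs114590429	C	A	SCN2A	-0.038	0.006	3.03E-10	0.005	0.019	.799	468924	208.52
rs1160545	T	C	LINC01104	-0.029	0.004	1.14E-13	-0.017	0.015	.256	525490	284.96
rs12062845	C	A	DPYD	-0.028	0.004	2.41E-11	-0.007	0.016	.638	442658	186.96
rs12324720	A	G	HERC1	-0.027	0.005	3.53E-09	0.038	0.017	.026	521894	148.87
rs12617870	G	T	PCGEM1	-0.026	0.004	6.62E-14	-0.038	0.015	.010	524165	236.62
rs12678836	C	A	AC103409.1	-0.023	0.004	5.37E-11	-0.008	0.015	.591	442658	181.93
rs12962050	A	G	CELF4	-0.023	0.004	1.18E-10	-0.002	0.016	.913	468924	170.13
rs13235840	A	T	EXOC4	-0.031	0.005	3.48E-10	0.020	0.018	.269	468924	200.61
rs1375561	C	T	CADM2	-0.023	0.004	2.55E-10	-0.026	0.015	.071	525488	168.79
rs1391954	G	T	GRM5	-0.025	0.004	1.51E-09	0.008	0.014	.598	468924	217.28
rs144155998	TA	T	RNU6-692P	-0.043	0.006	1.3E-14	-0.019	0.019	.311	526370	332.04
rs148544378	T	C	RIT2	-0.088	0.014	6.55E-11	-0.123	0.109	.258	442658	224.21
rs17025214	T	C	HTR1F	-0.022	0.004	4.31E-09	0.019	0.016	.235	525491	145.78
rs17621391	C	T	MKRN1	-0.024	0.004	2.11E-09	-0.045	0.017	.007	442658	157.98
rs1860337	T	C	MARCHF10	-0.025	0.004	9.08E-11	-0.010	0.015	.497	525485	212.09
rs1947066	G	A	GABRA6	-0.03	0.004	8.54E-12	-0.008	0.019	.656	442658	200.49
rs197439	A	G	INKA2	-0.026	0.004	3.29E-11	-0.026	0.014	.071	468924	228.28
rs1999065	C	T	TLR4	-0.025	0.004	1.24E-11	-0.014	0.015	.327	442658	196.93
rs2173650	T	G	TESC	-0.032	0.005	3.62E-09	-0.002	0.020	.918	468924	182.84
rs2229383	T	G	ILF3	-0.029	0.004	6.4E-13	-0.010	0.016	.543	468924	274.52
rs249960	G	A	ERAP1	-0.03	0.005	2.43E-09	-0.005	0.019	.788	468924	188.68
rs2529484	G	C	IMMP2L	-0.022	0.004	1.39E-09	0.005	0.015	.747	468830	155.25
rs262890	A	G	HTR1A	-0.034	0.004	2.06E-16	-0.016	0.015	.279	468924	341.92
rs2783992	T	C	SMARCA2	-0.024	0.004	3.36E-10	0.003	0.015	.831	525491	201.55
rs2964252	A	G	LINC01470	-0.024	0.004	3.16E-10	-0.018	0.015	.241	468924	175.31
rs34864022	A	G	LINC01239	-0.048	0.008	4.71E-10	0.042	0.031	.168	521893	200.00
rs36079846	T	C	VWC2L	-0.024	0.004	4.52E-10	-0.006	0.015	.658	469809	202.42
rs3759344	G	A	MLF2	-0.045	0.006	4.26E-13	0.008	0.026	.748	484638	270.26
rs396321	T	C	APC	-0.021	0.004	1.29E-09	-0.007	0.014	.652	442658	155.14
rs4303732	C	T	LINC01104	-0.027	0.004	5.37E-14	-0.017	0.015	.256	525491	246.80
rs4416502	G	A	ART3	-0.029	0.005	1.38E-09	-0.029	0.017	.089	468924	189.48
rs4483592	C	T	PACS1	-0.036	0.005	3.97E-12	0.006	0.019	.737	525491	249.01
rs4551799	A	G	FAM86C1	-0.024	0.004	6.91E-10	-0.013	0.016	.422	442658	183.04
rs558134	T	C	PHACTR1	-0.023	0.004	5.05E-10	-0.004	0.015	.782	468924	176.20
rs56151256	C	A	LINGO1	-0.029	0.004	1.17E-10	-0.034	0.018	.059	219777	222.06
rs566017137	C	G	NR4A2	-0.066	0.011	1.23E-09	-0.044	0.040	.281	525479	212.88
rs62131183	A	G	SIX3-AS1	-0.054	0.009	3.31E-09	0.025	0.034	.471	525491	183.92
rs62151809	C	T	ZBTB46	-0.023	0.004	3.9E-09	0.010	0.014	.473	524166	184.58
rs62244886	G	C	FOXP1	-0.024	0.004	1.24E-09	-0.021	0.015	.155	468924	194.01
rs6457816	T	C	PPARD	-0.041	0.007	3.97E-09	0.026	0.046	.572	468924	145.91
rs6685030	A	G	DNM3	-0.022	0.004	5.27E-10	-0.003	0.014	.810	468924	170.11
rs68049022	C	T	RPL17P35	-0.031	0.005	6.18E-11	-0.006	0.020	.763	243769	218.15
rs73420302	C	G	CBX8	-0.03	0.005	3.04E-09	-0.007	0.016	.662	469809	186.25
rs73581580	G	A	EXD3	-0.037	0.006	1.94E-10	0.028	0.018	.132	468924	209.41
rs7430216	C	T	LOC107986099	-0.025	0.004	2.5E-09	-0.009	0.017	.598	523876	152.49
rs7432837	T	C	NSUN3	-0.024	0.004	3.24E-09	0.003	0.016	.849	468924	155.27
rs743699	A	G	RGS12	-0.027	0.004	1.18E-09	0.013	0.016	.433	442658	196.02
rs7613360	C	T	ACTBP13	-0.032	0.004	6.92E-16	-0.026	0.016	.103	468924	344.97
rs7615206	T	C	MST1R	-0.035	0.004	1.5E-22	-0.028	0.015	.064	442658	422.94
rs76267866	A	T	SAMSSON	-0.03	0.005	3.53E-10	-0.004	0.018	.842	468924	208.79
rs78140587	G	A	KRT8P5	-0.062	0.01	5.83E-10	0.012	0.040	.764	512111	212.84
rs78394231	T	C	PDSS2	-0.038	0.007	3.53E-09	-0.036	0.023	.121	468924	179.74
rs7946119	C	T	NA	0.04	0.006	5.37E-11	-0.031	0.014	.032	482490	541.01
rs7969719	C	T	MYO1H	-0.027	0.004	4.46E-13	0.005	0.017	.775	468924	220.75
rs841020	C	T	GPR26	-0.027	0.004	1.15E-09	-0.015	0.016	.344	442658	159.25
rs9513416	G	A	FARP1	-0.028	0.005	4.1E-09	-0.007	0.022	.737	243411	147.62
rs9821299	G	A	CYP51A1P1	-0.029	0.005	3.63E-09	-0.027	0.018	.133	468924	178.56
rs9867121	A	C	ZBTB20	-0.032	0.005	2.02E-10	0.047	0.019	.015	468924	215.60
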