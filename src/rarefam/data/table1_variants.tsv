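variant_number	gene	chrom	pos	protein_change	rsid	fam6_carriers	fam6_affected	fam8_carriers	fam8_affected	linkage_z_fam6	linkage_z_iceland	control_maf	nordic_maf	max_public_maf
1	ANKRD50	chr4	125593332	T367M	rs140232140	3	8	NA	NA	NA	NA	0.0024	NA	0.0091
2	CHD3	chr17	7810250	A1523T	rs148451716	4	8	NA	NA	NA	1.79	0	NA	0.0003
3	FAT4	chr4	126238305	P247T	rs191329848	3	8	NA	NA	NA	NA	0.0016	0.0061	0.0042
4	KIR2DS4	chr19	55358686	I255L	rs112697729	6	8	1	7	NA	2.06	0	0.1689	NA
5	NUP214	chr9	134027138	I765V	rs61756081	3	8	NA	NA	1.3	NA	NA	0.012	0.0097
6	PDHA2	chr4	96762158	R286P	rs147966234	3	8	NA	NA	NA	NA	0.0071	0.0241	0.0091
7	SLC5A9	chr1	48694594	G103R	rs61746559	4	8	2	7	1.13	2.4	0.0071	0.006	0.0525
8	XRCC6BP1	chr12	58350618	A229V	rs117230607	6	8	NA	NA	NA	NA	0.0063	0.0183	0.0053
9	TPRA1	chr3	127292588	E300K	rs372625321	NA	NA	3	7	NA	NA	NA	NA	0.00008
10	KRTAP4-9	chr17	39261693	D18V	rs113059833	8	8	4	7	NA	NA	0	0.3765	0.1879
11	MPHOSPH8	chr13	20224319	E499K	rs147594834	NA	NA	3	7	NA	NA	0.008	NA	0.003
12	NOTCH1	chr9	139404360	D932N	rs758642073	NA	NA	5	7	NA	NA	0	NA	0.0002
13	PABPC3	chr13	25670676	A114T	rs117014540	NA	NA	3	7	NA	NA	0.0094	0.012	0.0044
14	WDR25	chr14	100847878	R206H	rs146976933	NA	NA	3	7	NA	NA	0.0031	NA	0.008
15	CLC	chr19	40225031	N65K	rs146776010	NA	NA	5	7	NA	2.06	0.0071	0.006	0.0176
16	DCLRE1C	chr10	14970085	H283N	rs772438042	NA	NA	5	7	1	NA	0	NA	0.000008
17	FAM71E1	chr19	50978724	L7F	rs185418641	NA	NA	4	7	NA	2.06	0.0063	0.0061	0.0073
18	FBXL14	chr12	1702929	N102H	rs117331652	NA	NA	5	7	NA	NA	0.0055	NA	0.0049
19	FAM8A1	chr6	17601340	G234R	rs202036280	NA	NA	3	7	NA	NA	NA	NA	0.00005
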