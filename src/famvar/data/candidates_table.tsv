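chrom	pos	ref	alt	gene	alt_freq	polyphen	sift	sift_indel	cadd_c	lod	family	unaff	logfc	fdr	seg_all_aneurysm	cross_family	go_tagged
1	6631121	C	T	TAS1R1	0.0001	.	damaging	.	16.77	1.08	D	0	NA	NA	1	0	0
1	15905363	G	T	AGMAT	0.0026	.	damaging	.	15.62	0.83	F	1	-0.127	0.952	1	0	0
1	28206319	G	A	C1orf38	0.0001	probably	damaging	.	17.71	0.57	G	0	NA	NA	1	0	0
1	28477192	T	C	PTAFR	0.0052	probably	damaging	.	20.80	0.57	G	0	-0.506	0.867	1	0	0
1	33760820	G	A	ZNF362	0.0000	probably	.	.	21.80	0.85	B	1	0.336	0.784	1	0	0
1	36638206	G	A	MAP7D1	0.0011	probably	damaging	.	34.00	0.47	D	0	0.157	0.792	1	0	0
1	111968011	G	A	OVGP1	0.0000	probably	damaging	.	12.85	0.57	G	1	-0.023	0.988	1	0	0
1	177899689	C	A	SEC16B	0.0010	probably	damaging	.	21.60	0.87	C	0	NA	NA	1	0	0
1	197072434	T	A	ASPM	0.0013	probably	.	.	14.55	0.57	G	1	1.195	0.642	1	0	0
1	204418411	C	T	PIK3C2B	0.0007	probably	damaging	.	35.00	0.57	G	1	-0.505	0.672	1	0	0
1	212799290	C	A	FAM71A	0.0000	probably	.	.	13.78	0.57	G	1	NA	NA	1	0	0
1	228290051	T	G	C1orf35	0.0093	probably	.	.	21.10	-0.29	A	0	-0.079	0.934	1	0	0
2	10186509	C	T	KLF11	0.0003	probably	damaging	.	14.69	1.41	A	0	-0.129	0.892	1	0	0
2	55825844	A	G	SMEK2	0.0026	probably	damaging	.	23.90	1.43	E	0	-0.222	0.631	1	0	0
2	73718061	A	G	ALMS1	0.0000	probably	damaging	.	12.02	1.13	D	0	-0.264	0.749	1	0	0
2	74757348	T	C	HTRA2	0.0030	probably	damaging	.	11.98	1.43	E	0	0.267	0.595	1	0	0
2	161029157	G	C	ITGB6	0.0001	probably	damaging	.	17.45	-0.84	G	1	NA	NA	0	0	0
3	126137556	G	A	CCDC37	0.0052	probably	.	.	12.36	-0.84	G	2	NA	NA	0	0	0
3	180334458	C	T	CCDC39	0.0026	probably	.	.	20.70	0.22	A	1	0.167	0.882	1	0	0
3	186508024	A	C	RFC4	0.0000	.	damaging	.	12.98	0.83	F	1	0.125	0.906	1	0	0
4	106158134	C	T	TET2	0.0000	probably	damaging	.	12.41	0.57	G	1	-0.231	0.878	1	0	0
4	106639176	T	A	GSTCD	0.0047	probably	.	.	22.90	0.57	G	1	-0.199	0.781	1	1	0
5	11018087	T	C	CTNND2	0.0000	probably	.	.	25.80	-0.29	A	0	-1.940	0.401	1	0	0
5	140801897	C	T	PCDHGA11	0.0007	.	damaging	.	18.54	0.57	G	1	-0.587	0.624	0	0	0
5	140955835	C	T	DIAPH1	0.0007	probably	.	.	36.00	0.57	G	1	0.344	0.612	0	0	0
5	149901055	G	A	NDST1	0.0036	probably	.	.	18.54	1.43	E	0	-0.157	0.806	1	0	0
5	157053610	T	C	SOX30	0.0013	probably	.	.	15.84	0.83	F	0	NA	NA	1	0	0
6	13316909	G	T	TBC1D7	0.0042	probably	damaging	.	23.60	0.86	G	1	-0.372	0.758	1	0	0
6	149856802	C	T	PPIL4	0.0000	probably	damaging	.	34.00	-0.29	A	0	0.100	0.900	1	0	0
6	159420630	A	T	RSPH3	0.0002	probably	damaging	.	15.37	0.57	G	1	-0.140	0.858	0	0	0
6	167709705	G	A	UNC93A	0.0052	probably	.	.	24.10	0.85	B	1	NA	NA	0	0	0
6	168317794	A	C	MLLT4	0.0000	probably	damaging	.	26.90	0.57	G	1	-0.150	0.884	1	0	0
8	72958750	T	A	TRPA1	0.0000	probably	.	.	14.64	-0.96	G	0	NA	NA	0	0	0
9	21166077	T	C	IFNA21	0.0002	.	damaging	.	10.42	1.12	D	0	NA	NA	1	0	0
9	35404008	G	A	UNC13B	0.0006	probably	damaging	.	34.00	0.83	F	1	-0.377	0.658	1	0	0
10	13240791	C	A	MCM10	0.0049	probably	.	.	17.17	0.85	B	1	1.318	0.563	0	0	0
10	47087309	G	C	PPYR1	0.0000	probably	damaging	.	15.45	0.57	G	1	NA	NA	1	0	0
10	82187167	G	A	C10orf58	0.0013	probably	.	.	36.00	0.56	G	1	NA	NA	0	0	0
10	105218301	C	G	CALHM1	0.0001	probably	.	.	16.88	-0.29	A	1	NA	NA	1	0	0
10	105727572	C	G	SLK	0.0000	probably	damaging	.	20.60	-0.29	A	1	0.182	0.774	1	0	0
10	105797397	G	A	COL17A1	0.0005	.	damaging	.	14.75	0.57	G	1	NA	NA	0	0	1
10	105893436	T	G	WDR96	0.0005	probably	.	.	23.90	-0.29	A	1	0.048	0.988	1	0	0
11	400124	C	G	PKP3	0.0013	probably	damaging	.	12.37	-0.71	G	0	NA	NA	1	0	0
11	73074872	G	A	ARHGEF17	0.0003	probably	damaging	.	18.47	1.13	D	0	0.162	0.931	1	0	0
11	108277861	C	T	C11orf65	0.0064	probably	damaging	.	21.30	1.13	C	1	NA	NA	1	0	0
11	124742851	G	A	ROBO3	0.0004	probably	damaging	.	20.20	1.31	A	0	-0.019	0.993	1	0	0
11	126147035	T	G	FOXRED1	0.0013	probably	damaging	.	18.40	-0.58	F	1	-0.152	0.815	1	0	0
12	2968094	G	T	FOXM1	0.0000	probably	damaging	.	13.37	0.29	D	0	0.885	0.615	1	0	1
12	12630140	T	G	DUSP16	0.0026	probably	.	.	16.34	-0.69	B	2	-0.324	0.686	1	1	0
12	49498284	T	G	LMBR1L	0.0040	probably	.	.	16.10	0.83	F	2	0.156	0.824	1	1	0
12	56335802	T	C	DGKA	0.0000	.	damaging	.	17.40	1.11	D	0	0.551	0.544	0	0	0
12	96374381	C	A	HAL	0.0006	probably	damaging	.	25.70	1.14	D	1	-0.479	0.922	1	1	0
12	126139069	C	T	TMEM132B	0.0002	probably	damaging	.	10.88	1.14	D	0	-2.626	0.023	0	0	0
15	75014793	T	A	CYP1A1	0.0003	probably	damaging	.	14.09	0.83	F	1	NA	NA	1	0	0
16	449449	G	A	NME4	0.0000	.	damaging	.	11.74	0.85	B	1	-0.076	0.943	1	0	0
16	2133701	G	A	TSC2	0.0040	probably	.	.	12.84	0.85	B	1	-0.229	0.658	1	1	0
16	11785220	G	A	TXNDC11	0.0014	probably	.	.	18.28	0.85	B	1	0.134	0.896	1	0	0
16	20796338	G	A	ACSM3	0.0013	probably	damaging	.	22.00	0.57	G	0	0.751	0.496	0	0	0
16	53321892	A	G	CHD9	0.0076	.	damaging	.	18.22	0.65	G	0	0.095	0.910	0	0	0
17	5425076	A	G	NLRP1	0.0042	.	damaging	.	10.35	-0.56	D	0	0.293	0.727	1	0	0
17	48762223	G	A	ABCC3	0.0013	probably	damaging	.	22.70	0.85	B	0	-0.043	0.994	1	0	0
17	61432613	T	A	TANC2	0.0000	probably	damaging	.	25.00	0.85	B	0	-0.213	0.859	1	0	0
19	11598418	G	A	ZNF653	0.0000	.	damaging	.	16.16	1.41	A	1	0.168	0.829	1	0	0
19	13226094	G	A	TRMT1	0.0002	probably	damaging	.	20.70	1.41	A	1	0.222	0.737	1	0	0
19	57175814	C	G	ZNF835	0.0009	probably	.	.	18.91	0.86	G	1	-0.797	0.556	0	0	0
19	57723459	C	T	ZNF264	0.0000	probably	damaging	.	11.70	0.86	G	1	-0.132	0.882	0	0	0
20	44463002	A	G	SNX21	0.0000	probably	.	.	22.20	0.85	B	1	-0.220	0.797	1	0	0
6	153312343	TTTTA	T	MTRF1L	0.0000	.	.	damaging	14.77	0.57	G	1	-0.095	0.924	0	0	0
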