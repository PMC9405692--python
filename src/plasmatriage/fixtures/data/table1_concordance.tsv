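gene	chrom	pos	patient_id	ref	alt	diagnosis	gdna_all	gdna_alt	gdna_af	tumor_all	tumor_alt	tumor_af	ccfdna_all	ccfdna_alt	ccfdna_af
TP53	chr17	7577120	31	C	T	Glioblastoma, Grade 4	106	0	0	149	144	0.97	1219	11	0.009
SMARCA4	chr19	11170654	58	G	A	Primary Central Nervous System Lymphoma	49	0	0	55	23	0.42	602	9	0.015
SMARCA4	chr19	11144125	59	C	T	Anaplastic Thyroid Cancer Metastasis	203	0	0	77	55	0.71	1979	454	0.229
TP53	chr17	7579372	59	GC	G	Anaplastic Thyroid Cancer Metastasis	324	0	0	128	76	0.59	1783	435	0.244
SPEN	chr1	16260997	59	G	T	Anaplastic Thyroid Cancer Metastasis	237	0	0	141	82	0.58	2308	458	0.198
KMT2D	chr12	49438655	59	C	G	Anaplastic Thyroid Cancer Metastasis	214	0	0	153	31	0.20	2238	229	0.102
LTBP2	chr14	75078119	59	T	G	Anaplastic Thyroid Cancer Metastasis	20	0	0	15	9	0.60	279	50	0.179
NF1	chr17	29560103	59	GA	G	Anaplastic Thyroid Cancer Metastasis	176	0	0	164	42	0.26	2444	227	0.093
CDKN2A	chr9	21971193	59	GC	G	Anaplastic Thyroid Cancer Metastasis	148	0	0	95	66	0.69	1199	180	0.150
JAK3	chr19	17952151	59	G	T	Anaplastic Thyroid Cancer Metastasis	29	0	0	9	5	0.56	1246	270	0.217
NSD1	chr5	176720936	65	G	C	Adenocarcinoma Lung Metastasis	390	0	0	418	191	0.46	862	183	0.212
EPHA6	chr3	96728829	71	G	GTT	Glioblastoma, Grade 4	11	0	0	23	3	0.13	618	14	0.023
SMARCA4	chr19	11144182	74	G	A	Astrocytoma Anaplasticum, Grade 3	43	0	0	259	76	0.29	1602	17	0.011
EGFR	chr7	55210075	74	T	G	Astrocytoma Anaplasticum, Grade 3	123	0	0	3020	1514	0.50	1694	427	0.252
PCSK7;TAGLN	chr11	117076708	108	T	C	Glioblastoma, Grade 4	12	0	0	67	10	0.15	1539	340	0.221
NF1	chr17	29563087	126	T	G	Glioblastoma, Grade 4	67	0	0	112	3	0.03	2141	36	0.017
TCF3	chr19	1619749	126	A	AGGGTG	Glioblastoma, Grade 4	38	0	0	73	15	0.21	1281	310	0.242
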