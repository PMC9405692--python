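gene	chrom	pos	patient_id	rsid	maf	af_1000g	af_gnomad	clinsig	diagnosis	gdna_all	gdna_alt	gdna_af	ccfdna_all	ccfdna_alt	ccfdna_af
APC	chr5	112177901	6	rs752654519	-	-	-	pathogenic/likely pathogenic	Glioblastoma, Grade 4	225	0	0	201	5	0.0249
TSC2	chr16	2098642	11	rs397515228	-	-	-	pathogenic	Diffuse Glioma, Grade 2	204	0	0	303	6	0.0198
APC	chr5	112111411	11	rs886039642	-	-	-	pathogenic/likely pathogenic	Diffuse Glioma, Grade 2	168	0	0	172	4	0.0233
TSC2	chr16	2136203	22	rs45517360	-	-	-	pathogenic	Glioblastoma, Grade 4	53	0	0	101	6	0.0594
JAK3	chr19	17950375	30	rs145751599	0	0.0004	2e-05	uncertain significance	Glioblastoma, Grade 4	212	0	0	200	4	0.02
NF1	chr17	29677233	31	rs377662483	0	0.0002	2e-05	uncertain significance	Glioblastoma, Grade 4	129	0	0	814	9	0.0111
NF1	chr17	29654553	33	rs876657714	-	-	-	pathogenic	Glioblastoma, Grade 4	252	0	0	470	4	0.00851
TP53	chr17	7577586	33	rs587781589	-	-	-	pathogenic	Glioblastoma, Grade 4	239	0	0	345	3	0.0087
NSD1	chr5	176637449	33	rs587784080	-	-	-	pathogenic	Glioblastoma, Grade 4	250	0	0	557	5	0.00898
EGFR	chr7	55233043	34	rs139236063	-	-	4e-06	likely pathogenic	Glioblastoma, Grade 4	120	0	0	2897	39	0.0135
NSD1	chr5	176709524	50	rs587784169	-	-	-	pathogenic	Diffuse Astrocytoma, Grade 2	154	0	0	428	4	0.00935
NSD1	chr5	176696631	53	rs794727176	-	-	-	pathogenic	Glioblastoma, Grade 4	239	0	0	335	3	0.00896
NF1	chr17	29486070	55	rs746824139	-	-	0	pathogenic	Glioblastoma, Grade 4	144	0	0	424	5	0.0118
PTEN	chr10	89717695	64	rs190070312	-	-	-	pathogenic	Glioblastoma, Grade 4	246	0	0	436	5	0.0115
PTEN	chr10	89711900	65	rs121913294	-	-	-	likely pathogenic	Adenocarcinoma Lung Metastasis	139	0	0	352	3	0.00852
RECQL4	chr8	145741409	68	rs549497811	0	0.0002	2e-05	uncertain significance	Glioblastoma, Grade 4	240	0	0	563	9	0.016
BRAF	chr7	140454008	70	rs397516894	-	-	-	pathogenic	Glioblastoma, Grade 4	228	0	0	372	4	0.0108
NF1	chr17	29562981	70	rs376576925	-	-	4e-06	pathogenic	Glioblastoma, Grade 4	195	0	0	613	6	0.00979
NF1	chr17	29560088	70	rs878853884	-	-	-	pathogenic	Glioblastoma, Grade 4	118	0	0	626	8	0.0128
MTOR	chr1	11184573	79	rs587777894	-	-	-	pathogenic	Glioblastoma with Oligodendroglioma Component, Grade 4	133	0	0	250	8	0.032
NSD1	chr5	176673711	79	rs570278338	-	-	-	pathogenic	Glioblastoma with Oligodendroglioma Component, Grade 4	65	0	0	132	2	0.0152
PTEN	chr10	89692793	79	rs786204927	-	-	-	likely pathogenic	Glioblastoma with Oligodendroglioma Component, Grade 4	99	0	0	180	7	0.0389
NF1	chr17	29677228	82	rs533110479	0	0.0002	3e-05	uncertain significance	Glioblastoma, Grade 4	243	0	0	436	5	0.0115
KMT2D	chr12	49438067	83	rs886043414	-	-	-	pathogenic	Glioblastoma, Grade 4	144	0	0	143	2	0.014
TP53	chr17	7579529	85	rs876658483	-	-	-	pathogenic	Glioblastoma, Grade 4	198	0	0	347	4	0.0115
TSC2	chr16	2114342	85	rs45517179	-	-	-	pathogenic	Glioblastoma, Grade 4	248	0	0	393	4	0.0102
MED12	chrX	70357138	85	rs762659794	0	0.0003	6e-06	uncertain significance	Glioblastoma, Grade 4	115	0	0	161	4	0.0248
PIK3CA	chr3	178952085	86	rs121913279	-	-	4e-06	pathogenic FDA recognized	Giant Cell Glioblastoma, Grade 4	245	0	0	139	2	0.0144
NOTCH1	chr9	139395108	86	rs371414501	0	0.0002	2e-05	uncertain significance	Giant Cell Glioblastoma, Grade 4	178	0	0	165	3	0.0182
SMARCA4	chr19	11094931	86	rs563079629	0	0.0002	5e-05	uncertain significance	Giant Cell Glioblastoma, Grade 4	58	0	0	136	5	0.0368
NF1	chr17	29588751	87	rs760703505	-	-	8e-06	pathogenic/likely pathogenic	Glioblastoma, Grade 4	241	0	0	485	4	0.00825
PTEN	chr10	89720768	93	rs746930141	-	-	-	pathogenic	Glioblastoma, Grade 4	70	0	0	199	2	0.0101
APC	chr5	112173704	99	rs587779783	-	-	-	pathogenic	Diffuse Astrocytoma, Grade 2	250	0	0	643	6	0.00933
NF1	chr17	29490394	100	rs199474752	-	-	-	likely pathogenic	Glioblastoma, Grade 4	168	0	0	356	3	0.00843
BRAF	chr7	140453137	105	rs121913378	-	-	-	likely pathogenic	Pleomorphic Xanthoastrocytoma, Grade 2	209	0	0	273	8	0.0293
PTEN	chr10	89711968	107	rs587776670	-	-	-	pathogenic	Glioblastoma, Grade 4	104	0	0	482	4	0.0083
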