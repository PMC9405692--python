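gene	patient_id	rsid	cosmic_cns_count	polyphen	gmaf	clinsig	diagnosis	gdna_all	gdna_alt	gdna_af	ccfdna_all	ccfdna_alt	ccfdna_af	somatic_af_other
PTEN	2	rs12573787	-	-	0.16	benign	Oligoastrocytoma, Grade 2	60	0	0.00	255	8	0.031	0.6923
PTEN	32	rs12573787	-	-	0.16	benign	Oligodendroglioma Anaplasticum, Grade 3	79	1	0.01	150	62	0.413	0.6923
PTEN	65	rs12573787	-	-	0.16	benign	Adenocarcinoma Lung Metastasis	55	1	0.02	61	33	0.541	0.6923
PTEN	85	rs12573787	-	-	0.16	benign	Glioblastoma, Grade 4	56	1	0.02	260	140	0.538	0.6923
PTEN	109	rs12573787	-	-	0.16	benign	Anaplastic Pleomorphic Xantoastrocytoma, Grade 3	57	0	0.00	168	13	0.077	0.6923
PTEN	110	rs12573787	-	-	0.16	benign	Glioblastoma, Grade 4	39	2	0.05	234	144	0.615	0.6923
PTEN	111	rs12573787	-	-	0.16	benign	Glioblastoma, Grade 4	107	1	0.01	160	68	0.425	0.6923
PTEN	117	rs12573787	-	-	0.16	benign	Glioblastoma, Grade 4	73	1	0.01	299	144	0.482	0.6923
PTEN	118	rs12573787	-	-	0.16	benign	Glioblastoma, Grade 4	40	1	0.03	224	114	0.509	0.6923
PTEN	121	rs12573787	-	-	0.16	benign	Giant Cell Glioblastoma, Grade 4	52	0	0.00	340	164	0.482	0.6923
TP53	90	rs121913343	131	D	-	pathogenic/likely pathogenic	Glioblastoma, Grade 4	147	3	0.02	1313	27	0.021	0.2619
EGFR	64	rs1057519828	14	D	-	likely pathogenic	Glioblastoma, Grade 4	225	0	0.00	612	22	0.036	0.4502
EGFR	64	rs149840192	36	D	-	likely pathogenic	Glioblastoma, Grade 4	181	3	0.02	703	9	0.013	0.248
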