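gene	chrom	pos	ref	alt	patient_id	rsid	cosmic_registered	clinsig	diagnosis	gdna_all	gdna_alt	gdna_af	ccfdna_all	ccfdna_alt	ccfdna_af	n_patients_somatic
SMARCA4	19	11144125	C	T	59	-	yes	-	Anaplastic Thyroid Cancer Metastasis	186	0	0	1979	454	0.229409	1
PIK3CA	3	178952085	A	G	86	rs121913279	-	likely pathogenic	Giant Cell Glioblastoma, Grade 4	245	0	0	139	2	0.014388	1
EPHA6	3	97365038	G	A	118	rs301948	-	-	Glioblastoma, Grade 4	199	0	0	1328	86	0.064759	1
EPHA6	3	97365074	A	G	118	rs301949	yes	-	Glioblastoma, Grade 4	179	0	0	1611	103	0.063935	1
EGFR	7	55210075	T	G	74	-	yes	-	Astrocytoma Anaplasticum, Grade 3	229	0	0	1694	427	0.252066	2
EGFR	7	55210075	T	G	114	-	yes	-	Astrocytoma, Grade 3	247	1	0.004	274	3	0.010949	2
EGFR	7	55224307	C	T	114	-	yes	likely pathogenic	Astrocytoma, Grade 3	245	0	0	417	9	0.021583	1
EGFR	7	55221822	C	T	64	rs149840192	yes	-	Glioblastoma, Grade 4	181	3	0.0166	703	9	0.012802	3
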