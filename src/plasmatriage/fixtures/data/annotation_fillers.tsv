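chrom	pos	ref	alt	rsid	maf	af_1000g	af_gnomad	clinsig	cosmic_registered	cosmic_cns_count	sift	coding
ctg1	10010	A	G	rsSYN0001	0.21	0.16	0.18	benign	no	0	0.62	yes
ctg1	12310	C	T	rsSYN0002	-	-	-	-	yes	5	0.01	yes
ctg2	10060	G	A	rsSYN0003	-	-	-	-	no	0	0.5	yes
ctg2	12360	T	C	rsSYN0004	-	0.0002	2e-05	uncertain significance	yes	3	0.02	yes
ctg3	10110	G	C	rsSYN0005	-	-	-	-	no	0	0.01	no
ctg1	14610	T	A	rsSYN0006	-	-	4e-06	pathogenic	yes	12	0.0	yes
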