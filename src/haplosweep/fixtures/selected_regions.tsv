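chromosome	start_bp	end_bp	haplops_score	population	snp_position_bp	rsid	risk_allele	risk_allele_is_ancestral	haplotype_frequency	allele_frequency	found_on_haplotype	nearest_genes
2	43282562	43910360	0.017	CHD	43586327	rs7578597	T	Y	0.45	0.994	Y	THADA
2	43301270	43958429	0.008	CHS	43586327	rs7578597	T	Y	0.45	1	Y	THADA
7	126647066	127610096	0.021	CHB	127034139	rs10229583	G	Y	0.40	0.798	Y	ARF5,PAX4,SND1
7	126647066	127610096	0.021	CHB	126952194	rs6467136	G	Y	0.40	0.775	Y	GCC1,PAX4
7	126716840	127589178	0.022	CHS	127034139	rs10229583	G	Y	0.45	0.775	Y	ARF5,PAX4,SND1
7	126716840	127589178	0.022	CHS	126952194	rs6467136	G	Y	0.45	0.801	Y	GCC1,PAX4
7	126720180	127631331	0.024	CHD	127034139	rs10229583	G	Y	0.45	0.829	Y	ARF5,PAX4,SND1
7	126720180	127631331	0.024	CHD	126952194	rs6467136	G	Y	0.45	0.780	Y	GCC1,PAX4
7	126735606	127628256	0.015	JPT	127034139	rs10229583	G	Y	0.50	0.866	Y	ARF5,PAX4,SND1
7	126735606	127628256	0.015	JPT	126952194	rs6467136	G	Y	0.50	0.818	Y	GCC1,PAX4
10	92947202	95385717	0.032	JPT	94455539	rs5015480	C	Y	0.05	0.186	N	HHEX,IDE
10	92947202	95385717	0.032	JPT	94452862	rs1111875	C	N	0.05	0.349	N	HHEX
15	61999328	62941185	0.033	CHS	60183681	rs7172432	A	N	0.60	0.330	N	C2CD4A,C2CD4B
15	62122278	62938688	0.003	JPT	60183681	rs7172432	A	N	0.70	0.552	N	C2CD4A,C2CD4B
15	62303982	62934451	0.012	CHD	60183681	rs7172432	A	N	0.80	0.631	N	C2CD4A,C2CD4B
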