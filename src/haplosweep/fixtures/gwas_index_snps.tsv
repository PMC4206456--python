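rsid	chromosome	position_bp	no_risk_allele	risk_allele	risk_allele_frequency	nearest_genes	p_value	odds_ratio	trait	reported_east_asian	reported_european	ancestral_allele
rs7578597	2	43586327	C	T	0.9	THADA	1e-9	1.15	T2D	N	Y	T
rs10229583	7	127034139	A	G	0.825	ARF5,PAX4,SND1	2e-10	1.14	T2D	Y	N	G
rs6467136	7	126952194	A	G	0.79	GCC1,PAX4	5e-11	1.11	T2D	Y	N	G
rs5015480	10	94455539	T	C	NR	HHEX,IDE	1e-15	1.18	T2D	N	Y	C
rs1111875	10	94452862	T	C	0.52	HHEX	7e-12	1.21	T2D	Y	Y	T
rs7172432	15	60183681	G	A	0.58	C2CD4A,C2CD4B	9e-14	1.11	T2D	Y	N	G
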