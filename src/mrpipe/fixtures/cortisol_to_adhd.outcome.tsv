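snp	effect_allele	other_allele	eaf	beta	se	pval	n
rs1075533	A	G			0.0302	0.5883	55347
rs12589136	T	G			0.0159	0.6756	55347
rs1340395	T	C			0.0253	0.6687	55347
rs4400057	A	G			0.0200	0.6623	55347
rs6830	A	G			0.0141	0.8234	55347
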