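snp	effect_allele	other_allele	eaf	beta	se	pval	n
rs1075533	A	G	0.037	-0.17158	0.0347	7.740e-07	12597
rs12589136	T	G	0.217	0.10340	0.0148	3.320e-12	12597
rs1340395	T	C	0.926	-0.12635	0.0259	1.090e-06	12597
rs4400057	A	G	0.912	-0.31933	0.0651	9.460e-07	12597
rs6830	A	G	0.320	-0.06318	0.0133	1.940e-06	12597
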