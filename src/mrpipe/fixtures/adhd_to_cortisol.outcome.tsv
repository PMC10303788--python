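snp	effect_allele	other_allele	eaf	beta	se	pval	n
rs10262192	A	G		-0.004	0.0127	0.7447	12597
rs112984125	A	G		0.018	0.0134	0.1826	12597
rs1427829	G	A		0.015	0.0132	0.2508	12597
rs212178	A	G		0.025	0.0217	0.2428	12597
rs4858241	G	T		-0.029	0.0340	0.3880	12597
rs4916723	C	A		0.0005	0.0129	0.9662	12597
rs9677504	A	G		-0.044	0.0200	0.0273	12597
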