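snp	chr	pos	effect_allele	other_allele	eaf	beta	se	pval	n
rs10262192	7	114091753	A	G	0.4322	0.07320	0.0132	2.887e-08	55347
rs112984125	1	44237465	A	G	0.3120	-0.10601	0.0146	3.581e-13	55347
rs1427829	12	89760744	G	A	0.5575	-0.07990	0.0133	1.822e-09	55347
rs212178	16	72653326	A	G	0.9004	-0.11540	0.0200	7.677e-09	55347
rs4858241	3	20669071	G	T	0.3620	-0.07890	0.0140	1.740e-08	55347
rs4916723	5	87854395	C	A	0.4397	0.07660	0.0135	1.576e-08	55347
rs9677504	2	215181889	A	G	0.1100	0.11690	0.0206	1.391e-08	55347
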