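Genomic location (GRCh37)	Transcript	Protein ID	Variant	Protein change	Allele count	Homozygote count	Allele frequency	Variants categories
chr18: 29172937	NM_000371.4	NP_000362.1	c.148G>A	p.V50M	26	0	0.000103	Pathogenic
chr18: 29175120	NM_000371.4	NP_000362.1	c.238A>G	p.T80A	1	0	0.00000398	Pathogenic
chr18: 29175132	NM_000371.4	NP_000362.1	c.250T>C	p.F84L	1	0	0.00000398	Pathogenic
chr18: 29175144	NM_000371.4	NP_000362.1	c.262A>T	p.I88L	5	0	0.0000199	Likely pathogenic
chr18: 29178543	NM_000371.4	NP_000362.1	c.349G>T	p.A117S	2	0	0.00000795	Likely pathogenic
chr18: 29178618	NM_000371.4	NP_000362.1	c.424G>A	p.V142I	435	3	0.00174	Likely pathogenic
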