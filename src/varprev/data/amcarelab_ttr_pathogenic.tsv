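Genomic location (GRCh37)	Transcript	Protein ID	Variant	Protein change	Individual count	Number of homozygotes	Variants categories	Previously reported
chr18: 29172902	NM_000371.4	NP_000362.1	c.113A>G	p.D38G	4	0	Likely pathogenic	Yes
chr18: 29172937	NM_000371.4	NP_000362.1	c.148G>A	p.V50M	8	0	Pathogenic	Yes
chr18: 29172954	NM_000371.4	NP_000362.1	c.165G>T	p.K55N	1	0	Likely pathogenic	Yes
chr18: 29172988	NM_000371.4	NP_000362.1	c.199G>A	p.G67R	1	0	Likely pathogenic	Yes
chr18: 29175092	NM_000371.4	NP_000362.1	c.210T>A	p.S70R	1	0	Likely pathogenic	Yes
chr18: 29175096	NM_000371.4	NP_000362.1	c.214T>C	p.S72P	1	0	Likely pathogenic	Yes
chr18: 29175103	NM_000371.4	NP_000362.1	c.221A>C	p.E74A	1	0	Likely pathogenic	Yes
chr18: 29175106	NM_000371.4	NP_000362.1	c.224T>G	p.L75R	1	0	Likely pathogenic	Yes
chr18: 29175123	NM_000371.4	NP_000362.1	c.241G>A	p.E81K	3	0	Likely pathogenic	Yes
chr18: 29175172	NM_000371.4	NP_000362.1	c.290C>T	p.S97F	1	0	Likely pathogenic	Yes
chr18: 29175193	NM_000371.4	NP_000362.1	c.311T>A	p.I104N	1	0	Likely pathogenic	Yes
chr18: 29175207	NM_000371.4	NP_000362.1	c.325G>A	p.E109K	3	0	Likely pathogenic	Yes
chr18: 29178543	NM_000371.4	NP_000362.1	c.349G>T	p.A117S	5	0	Likely pathogenic	Yes
chr18: 29178595	NM_000371.4	NP_000362.1	c.401A>G	p.Y134C	1	0	Likely pathogenic	Yes
chr18: 29178618	NM_000371.4	NP_000362.1	c.424G>A	p.V142I	2	0	Likely pathogenic	Yes
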