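Genomic location (GRCh37)	Transcript	Protein ID	Variant	Protein change	Allele count	Variants categories
chr18: 29172937	NM_000371.3	NP_000362.1	c.148G>A	p.Val50Met	1	Pathogenic
chr18: 29178618	NM_000371.3	NP_000362.1	c.424G>A	p.Val142Ile	1	Likely pathogenic
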