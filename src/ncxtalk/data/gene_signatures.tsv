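gene_symbol	gene_class	chrom	signatures
NECTIN2	protein_coding	19	A
AC011481.2	lncRNA	19	B
TOMM40	protein_coding	19	B
APOE	protein_coding	19	B
APOC1	protein_coding	19	B
AL662844.2	pseudogene	6	C
HLA-C	protein_coding	6	C
HLA-DRB1	protein_coding	6	D;E
HLA-DQA1	protein_coding	6	D;E;F
TSBP1-AS1	lncRNA	6	D;F
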