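gene_symbol	disease	n_pmids
APOE	Alzheimer's disease	3042
APOE	Alzheimer's disease, late onset	431
APOE	Diabetes mellitus	87
APOE	Diabetes mellitus, non-insulin-dependent	83
APOE	Diabetes mellitus, insulin-dependent	14
APOC1	Alzheimer's disease	20
APOC1	Alzheimer's disease, late onset	5
APOC1	Diabetic nephropathy	1
TOMM40	Alzheimer's disease	92
TOMM40	Alzheimer's disease, late onset	24
TOMM40	Diabetes mellitus, non-insulin-dependent	4
NECTIN2	Alzheimer's disease	25
NECTIN2	Alzheimer's disease, late onset	6
NECTIN2	Diabetes mellitus, non-insulin-dependent	1
HLA-C	Alzheimer's disease	2
HLA-C	Diabetes mellitus, insulin-dependent	24
HLA-DQA1	Alzheimer's disease	1
HLA-DQA1	Diabetes mellitus, insulin-dependent	191
HLA-DQA1	Diabetes mellitus, non-insulin-dependent	3
HLA-DRB1	Alzheimer's disease	10
HLA-DRB1	Alzheimer's disease, late onset	1
HLA-DRB1	Diabetes mellitus, insulin-dependent	279
HLA-DRB1	Diabetes mellitus, non-insulin-dependent	17
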