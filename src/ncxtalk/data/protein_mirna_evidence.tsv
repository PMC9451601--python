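regulator	target	layer	evidence
hsa-miR-199a-5p	APOC1	protein_mirna	a,b
hsa-miR-199a-5p	HLA-DQA1	protein_mirna	a,b
hsa-miR-199a-5p	TOMM40	protein_mirna	a,b,c
hsa-miR-199a-5p	NECTIN2	protein_mirna	a,b
hsa-miR-199b-5p	APOC1	protein_mirna	a,d
hsa-miR-199b-5p	HLA-DQA1	protein_mirna	a,f
hsa-miR-199b-5p	TOMM40	protein_mirna	a,b,c
hsa-miR-199b-5p	NECTIN2	protein_mirna	a,b
hsa-miR-423-5p	HLA-C	protein_mirna	a,b
hsa-miR-423-5p	HLA-DQA1	protein_mirna	a,b
hsa-miR-423-5p	TOMM40	protein_mirna	a,b
hsa-miR-423-5p	NECTIN2	protein_mirna	a,b
hsa-miR-3184-5p	HLA-C	protein_mirna	a,b
hsa-miR-3184-5p	HLA-DQA1	protein_mirna	a,b
hsa-miR-3184-5p	TOMM40	protein_mirna	a,b
hsa-miR-3184-5p	NECTIN2	protein_mirna	a,b
hsa-miR-124-3p	APOC1	protein_mirna	a,d
hsa-miR-124-3p	HLA-DQA1	protein_mirna	a,b
hsa-miR-124-3p	TOMM40	protein_mirna	a,e
hsa-miR-506-3p	APOC1	protein_mirna	a,b
hsa-miR-506-3p	HLA-DQA1	protein_mirna	a,b
hsa-miR-506-3p	TOMM40	protein_mirna	a,b
hsa-miR-1321	APOC1	protein_mirna	a,b
hsa-miR-1321	HLA-DRB1	protein_mirna	a,b,c
hsa-miR-1321	TOMM40	protein_mirna	a,b
hsa-miR-4731-5p	APOC1	protein_mirna	a,b,c
hsa-miR-4731-5p	TOMM40	protein_mirna	a,b
hsa-miR-4731-5p	NECTIN2	protein_mirna	a,b
hsa-miR-491-5p	APOE	protein_mirna	a,e
hsa-miR-491-5p	HLA-C	protein_mirna	a,b,c
hsa-miR-491-5p	TOMM40	protein_mirna	a,b
hsa-miR-663a	APOE	protein_mirna	a,b,c,e
hsa-miR-663a	TOMM40	protein_mirna	a,b
hsa-miR-663a	NECTIN2	protein_mirna	a,b
hsa-miR-744-5p	APOE	protein_mirna	a,b
hsa-miR-744-5p	TOMM40	protein_mirna	a,b
hsa-miR-744-5p	NECTIN2	protein_mirna	a,b
hsa-miR-665	APOE	protein_mirna	a,b,c
hsa-miR-665	TOMM40	protein_mirna	a,b
hsa-miR-665	NECTIN2	protein_mirna	a,b
hsa-miR-1286	APOE	protein_mirna	a,e
hsa-miR-1286	HLA-DRB1	protein_mirna	a,b
hsa-miR-1286	TOMM40	protein_mirna	a,e
hsa-miR-1908-5p	APOE	protein_mirna	a,b,c,e
hsa-miR-1908-5p	TOMM40	protein_mirna	a,b
hsa-miR-1908-5p	NECTIN2	protein_mirna	a,b
hsa-miR-873-5p	HLA-C	protein_mirna	a,c
hsa-miR-873-5p	TOMM40	protein_mirna	a,b
hsa-miR-873-5p	NECTIN2	protein_mirna	a,c
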