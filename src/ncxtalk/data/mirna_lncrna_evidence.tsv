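regulator	target	layer	evidence
NEAT1	hsa-miR-124-3p	mirna_lncrna	S,L
AC069281.2	hsa-miR-124-3p	mirna_lncrna	S
XIST	hsa-miR-124-3p	mirna_lncrna	S,L
KCNQ1OT1	hsa-miR-124-3p	mirna_lncrna	S,L
AC010442.1	hsa-miR-124-3p	mirna_lncrna	S,L
AC010327.5	hsa-miR-124-3p	mirna_lncrna	S
NEAT1	hsa-miR-1286	mirna_lncrna	S
AC069281.2	hsa-miR-1286	mirna_lncrna	S
AC092127.1	hsa-miR-1286	mirna_lncrna	S
AC010327.5	hsa-miR-1286	mirna_lncrna	S
NEAT1	hsa-miR-1321	mirna_lncrna	S,L
AC069281.2	hsa-miR-1321	mirna_lncrna	S,L
XIST	hsa-miR-1321	mirna_lncrna	S,L
KCNQ1OT1	hsa-miR-1321	mirna_lncrna	S,L
AC010442.1	hsa-miR-1321	mirna_lncrna	S
AC092127.1	hsa-miR-1321	mirna_lncrna	S
SLC9A3-AS1	hsa-miR-1321	mirna_lncrna	S
KRTAP5-AS1	hsa-miR-1321	mirna_lncrna	S
STAG3L5P-PVRIG2P-PILRB	hsa-miR-1321	mirna_lncrna	S
LINC00963	hsa-miR-1321	mirna_lncrna	S
NEAT1	hsa-miR-1908-5p	mirna_lncrna	S
AC069281.2	hsa-miR-1908-5p	mirna_lncrna	S
XIST	hsa-miR-1908-5p	mirna_lncrna	S
AC092127.1	hsa-miR-1908-5p	mirna_lncrna	S
SLC9A3-AS1	hsa-miR-1908-5p	mirna_lncrna	S
KRTAP5-AS1	hsa-miR-1908-5p	mirna_lncrna	S
LINC00963	hsa-miR-1908-5p	mirna_lncrna	S
KCNQ1OT1	hsa-miR-199a-5p	mirna_lncrna	S,L
KRTAP5-AS1	hsa-miR-199a-5p	mirna_lncrna	S,L
STAG3L5P-PVRIG2P-PILRB	hsa-miR-199a-5p	mirna_lncrna	S
LINC00963	hsa-miR-199a-5p	mirna_lncrna	S
KCNQ1OT1	hsa-miR-199b-5p	mirna_lncrna	S,L
KRTAP5-AS1	hsa-miR-199b-5p	mirna_lncrna	S,L
STAG3L5P-PVRIG2P-PILRB	hsa-miR-199b-5p	mirna_lncrna	S
LINC00963	hsa-miR-199b-5p	mirna_lncrna	S
NEAT1	hsa-miR-3184-5p	mirna_lncrna	S,L
AC069281.2	hsa-miR-3184-5p	mirna_lncrna	S
XIST	hsa-miR-3184-5p	mirna_lncrna	S,L
KCNQ1OT1	hsa-miR-3184-5p	mirna_lncrna	S,L
AC010442.1	hsa-miR-3184-5p	mirna_lncrna	S
AC092127.1	hsa-miR-3184-5p	mirna_lncrna	S,L
SLC9A3-AS1	hsa-miR-3184-5p	mirna_lncrna	S
KRTAP5-AS1	hsa-miR-3184-5p	mirna_lncrna	S
AC010327.5	hsa-miR-3184-5p	mirna_lncrna	S
STAG3L5P-PVRIG2P-PILRB	hsa-miR-3184-5p	mirna_lncrna	S
NEAT1	hsa-miR-423-5p	mirna_lncrna	S,L
AC069281.2	hsa-miR-423-5p	mirna_lncrna	S
XIST	hsa-miR-423-5p	mirna_lncrna	S,L
KCNQ1OT1	hsa-miR-423-5p	mirna_lncrna	S,L
AC010442.1	hsa-miR-423-5p	mirna_lncrna	S,L
AC092127.1	hsa-miR-423-5p	mirna_lncrna	S,L
SLC9A3-AS1	hsa-miR-423-5p	mirna_lncrna	S,L
KRTAP5-AS1	hsa-miR-423-5p	mirna_lncrna	S,L
AC010327.5	hsa-miR-423-5p	mirna_lncrna	S,L
STAG3L5P-PVRIG2P-PILRB	hsa-miR-423-5p	mirna_lncrna	S,L
NEAT1	hsa-miR-4731-5p	mirna_lncrna	S,L
AC069281.2	hsa-miR-4731-5p	mirna_lncrna	S,L
XIST	hsa-miR-4731-5p	mirna_lncrna	S,L
KCNQ1OT1	hsa-miR-4731-5p	mirna_lncrna	S,L
AC092127.1	hsa-miR-4731-5p	mirna_lncrna	S
SLC9A3-AS1	hsa-miR-4731-5p	mirna_lncrna	S
KRTAP5-AS1	hsa-miR-4731-5p	mirna_lncrna	S
AC010327.5	hsa-miR-4731-5p	mirna_lncrna	S
LINC00963	hsa-miR-4731-5p	mirna_lncrna	S,L
NEAT1	hsa-miR-491-5p	mirna_lncrna	S,L
AC069281.2	hsa-miR-491-5p	mirna_lncrna	S
XIST	hsa-miR-491-5p	mirna_lncrna	S,L
KCNQ1OT1	hsa-miR-491-5p	mirna_lncrna	S,L
AC010442.1	hsa-miR-491-5p	mirna_lncrna	S,L
STAG3L5P-PVRIG2P-PILRB	hsa-miR-491-5p	mirna_lncrna	S
NEAT1	hsa-miR-506-3p	mirna_lncrna	S,L
AC069281.2	hsa-miR-506-3p	mirna_lncrna	S
XIST	hsa-miR-506-3p	mirna_lncrna	S,L
KCNQ1OT1	hsa-miR-506-3p	mirna_lncrna	S,L
AC010442.1	hsa-miR-506-3p	mirna_lncrna	S,L
AC010327.5	hsa-miR-506-3p	mirna_lncrna	S
NEAT1	hsa-miR-663a	mirna_lncrna	S
AC069281.2	hsa-miR-663a	mirna_lncrna	S
XIST	hsa-miR-663a	mirna_lncrna	S
AC092127.1	hsa-miR-663a	mirna_lncrna	S
SLC9A3-AS1	hsa-miR-663a	mirna_lncrna	S
KRTAP5-AS1	hsa-miR-663a	mirna_lncrna	S
LINC00963	hsa-miR-663a	mirna_lncrna	S
NEAT1	hsa-miR-665	mirna_lncrna	S,L
AC069281.2	hsa-miR-665	mirna_lncrna	S
XIST	hsa-miR-665	mirna_lncrna	S,L
KCNQ1OT1	hsa-miR-665	mirna_lncrna	S,L
SLC9A3-AS1	hsa-miR-665	mirna_lncrna	S
AC010327.5	hsa-miR-665	mirna_lncrna	S
STAG3L5P-PVRIG2P-PILRB	hsa-miR-665	mirna_lncrna	S
LINC00963	hsa-miR-665	mirna_lncrna	S,L
AC010442.1	hsa-miR-744-5p	mirna_lncrna	S
SLC9A3-AS1	hsa-miR-744-5p	mirna_lncrna	S
NEAT1	hsa-miR-873-5p	mirna_lncrna	S,L
XIST	hsa-miR-873-5p	mirna_lncrna	S,L
AC010442.1	hsa-miR-873-5p	mirna_lncrna	S
AC092127.1	hsa-miR-873-5p	mirna_lncrna	S,L
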