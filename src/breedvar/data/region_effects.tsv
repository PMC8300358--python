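# Published per-region effect counts for the cohort-homozygous breed-specific
# variants (SNP/INS/DEL columns), one row per genomic region class.
region	SNP	INS	DEL
UPSTREAM	7715	10497	7336
EXON	1138	1484	903
INTERGENIC	63497	84897	46518
INTRAGENIC	119	190	112
INTRON	21312	37272	19557
SPLICE_SITE	194	595	435
UTR5	174	307	197
UTR3	43	106	57
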