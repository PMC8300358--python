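# Published single-gene variant classification for the eqCD1a6 gene:
# counts of cohort-shared SNPs and INDELs per annotation category.
group	category	count
SNP	upstream	162
SNP	exon	51
SNP	intron	62
INDEL	upstream	19
INDEL	exon	0
INDEL	intron	2
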