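# Published per-sample variant tallies (GATK calls vs the horse reference):
# homozygous/heterozygous insertions, deletions and SNPs for five Jeju
# horses and one Thoroughbred.
sample_id	homo_INS	het_INS	homo_DEL	het_DEL	homo_SNP	het_SNP
Jeju_1	246788	199722	263896	201114	2404789	4304466
Jeju_2	235661	187896	254611	190505	2331653	4211637
Jeju_3	242743	193519	259821	196679	2415831	4312941
Jeju_4	238128	201288	255380	204404	2329651	4397561
Jeju_5	239981	195073	258247	196586	2369765	4355094
Thoroughbred	157841	142173	166728	122802	1740637	2202227
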