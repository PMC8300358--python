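# Published stage counts of the three-pass breed-specificity filter:
# variants shared by all five in-group samples, remaining after subtracting
# the outgroup sample, remaining after subtracting known-variant catalogs
# (SNPs only for the catalog pass), and the homozygous/heterozygous split
# of the final specific set.
stage	SNP	INS	DEL
shared_ingroup	2758242	233819	240738
after_outgroup	1244064	113498	114751
after_catalogs	408601	113498	114751
final_homozygous	94192	85394	75115
final_heterozygous	314409	28104	39636
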