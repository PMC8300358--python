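# Published two-channel digital-PCR well-count panel for the breed-specific
# marker assay: channel 1 (FAM) detects the in-group (Jeju horse) allele,
# channel 2 (Cy5/SFC620) the outgroup (Thoroughbred) allele. Concentrations
# (copies/uL), ratio and result are the instrument-software outputs.
species,sample_id,total_wells,valid_wells,ch1_pos,ch1_neg,ch1_conc,ch2_pos,ch2_neg,ch2_conc,ratio,result
Jeju horse,J01,20163,18781,653,18128,308.62,0,18781,0,0,Jeju horse
Jeju horse,J02,20163,18430,615,17815,295.98,0,18430,0,0,Jeju horse
Jeju horse,J03,20163,17464,624,16840,317.31,0,17464,0,0,Jeju horse
Jeju horse,J04,20163,18389,615,17774,296.65,0,18389,0,0,Jeju horse
Jeju horse,J05,20163,17790,258,17532,127.4,255,17535,125.91,1.01,Heterozygote
Jeju horse,J06,20163,16825,414,16411,217.27,0,16825,0,0,Jeju horse
Jeju horse,J07,20163,18703,256,18447,120.19,264,18439,123.98,0.97,Heterozygote
Jeju horse,J08,20163,17508,539,16969,272.7,0,17508,0,0,Jeju horse
Jeju horse,J09,20163,18835,549,18286,257.97,0,18835,0,0,Jeju horse
Jeju horse,J10,20163,19167,733,18434,340.06,0,19167,0,0,Jeju horse
Thoroughbred,R01,20163,18413,0,18413,0,213,18200,101.47,0,Thoroughbred
Thoroughbred,R02,20163,17219,0,17219,0,154,17065,78.35,0,Thoroughbred
Thoroughbred,R03,20163,18356,0,18356,0,588,17768,283.93,0,Thoroughbred
Thoroughbred,R04,20163,18365,228,18137,108.95,256,18109,122.42,0.89,Heterozygote
Thoroughbred,R05,20163,18890,0,18890,0,655,18235,307.76,0,Thoroughbred
Thoroughbred,R06,20163,17654,0,17654,0,468,17186,234.31,0,Thoroughbred
Thoroughbred,R07,20163,19244,0,19244,0,535,18709,245.88,0,Thoroughbred
Thoroughbred,R08,20163,17875,0,17875,0,553,17322,274.06,0,Thoroughbred
Thoroughbred,R09,20163,18125,0,18125,0,486,17639,237.03,0,Thoroughbred
Thoroughbred,R10,20163,17613,227,17386,113.13,260,17353,129.7,0.87,Heterozygote
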