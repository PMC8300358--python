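# Published whole-genome-resequencing read-mapping summary: five Jeju horses
# and one Thoroughbred mapped to the horse reference genome (equCab2).
# depth is fold coverage.
sample_id	group	total_reads	clean_reads	mapped_reads	depth
Jeju_1	Jeju	690508306	621253885	612618456	37.24
Jeju_2	Jeju	609871934	532985097	523657858	31.48
Jeju_3	Jeju	661791072	581568986	572263882	34.50
Jeju_4	Jeju	617836736	555881352	547987837	33.14
Jeju_5	Jeju	606111944	545197568	536038249	32.36
Thoroughbred	Thoroughbred	990419468	820451365	780311183	46.01
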