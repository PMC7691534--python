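# Benchmark fixture: reference counts for 10 clinically relevant cytobands,
# comparing a full-text literature index (total and exact-match references)
# against exact-match PubMed searches. Coordinates are 0-based half-open,
# UCSC cytoBand convention.
cytoband	chrom	start	end	disease	mm_total_refs	mm_exact_refs	pubmed_refs
11q23	chr11	110600000	121300000	Jacobsen syndrome, 11q23 deletion syndrome	7926	1625	490
14q32.2	chr14	95800000	100900000	Kagami-Ogata syndrome	2470	147	30
15q11.2	chr15	20500000	25500000	15q11.2 BP1-BP2 microdeletion syndrome, Burnside-Butler syndrome	4095	850	268
17p11.2	chr17	16100000	22700000	Smith-Magenis syndrome	3604	1093	403
17q12	chr17	33500000	39800000	17q12 microdeletion syndrome, 17q12 deletion and duplication syndrome	4677	619	169
18q21.1	chr18	45900000	50700000	Pitt-Hopkins syndrome	2525	344	71
22q11.2	chr22	17400000	25500000	22q11.2 deletion syndrome (22q11.2DS)	13363	4808	2086
22q13.3	chr22	43800000	50818467	Phelan-McDermid syndrome, 22q13.3 deletion syndrome	2882	545	116
2q22.3	chr2	143400000	147900000	Mowat-Wilson syndrome	1099	52	11
4q35.1	chr4	182300000	186200000	Terminal chromosome 4q deletion syndrome	2312	100	19
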