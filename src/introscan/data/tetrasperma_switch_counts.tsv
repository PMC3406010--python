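lineage	allele	n_pr_to_npr	n_npr_to_pr	total_codons
L1	mat_a	1308	798	283392
L1	mat_A	1531	795	283392
L4	mat_a	1828	1063	282819
L4	mat_A	1827	952	282819
L9	mat_a	2089	1277	282723
L9	mat_A	3300	2549	282723
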