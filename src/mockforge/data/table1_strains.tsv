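name	strain_id	genome_size_bp	gc_percent	rrs_copies	accessions	gram_stain
Bacillus subtilis	NBRC 13719	4295305	43.3	10	AP019714;AP019715
Bifidobacterium pseudocatenulatum	NBRC 113353	2277780	56.4	5	BJLC00000000
Clostridium butyricum	NBRC 13949	4705096	28.8	11	AP019716–AP019719
Corynebacterium striatum	NBRC 15291	3113921	59.1	4	BJLD00000000
Cutibacterium acnes subsp. acnes	NBRC 107605	2494738	60.0	3	AP019723
Enterocloster clostridioformis	NBRC 113352	5687315	48.9	5	BJLB00000000
Lactobacillus delbrueckii	NBRC 3202	1910306	50.1	8	AP019750
Staphylococcus epidermidis	NBRC 100911	2427041	32.3	6	AP019721;AP019722
Streptococcus mutans	NBRC 13955	2018796	36.9	5	AP019720
Acinetobacter radioresistens	NBRC 102413	3433938	41.4	6	AP019740–AP019748
Bacteroides uniformis	NBRC 113350	4989532	46.2	4	AP019724–AP019728
Comamonas terrigena	NBRC 13299	4673011	65.0	7	AP019749
Escherichia coli	NBRC 3301	4755096	50.8	7	CP048439;CP048440
Parabacteroides distasonis	NBRC 113806	5179960	45.0	7	AP019729
Pseudomonas putida	NBRC 14164	6156701	62.3	7	AP013070
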