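species	accession	location	tsd	xerC	spacer	xerD
Acinetobacter baumannii	CP018254	chromosomal_dif	ATAAT	TGTTCGTATAA	TGTATA	TTATGTTAAAT
Acinetobacter baumannii	CP091373	chromosomal_dif	ATAAT	TGTTCGCATAA	TGTATA	TTATGTTAAAT
Acinetobacter haemolyticus	CP031984	chromosomal_dif	GGTAA	ATTGCGCATAA	TGTATA	TTATGTTAAAT
Acinetobacter indicus	CP094254	chromosomal_dif	GACTG	ATTTCGTATAA	TGTATA	TTATGTTAAAC
Acinetobacter indicus	CP094254	secondary_dif	AGTCG	AATTCGCATAA	CAGCCA	TTATGTTAAAT
Acinetobacter sp.	CP028561	chromosomal_dif	TAATA	ATTGCGTATAA	TGTATA	TTATGTTAAAT
Acinetobacter sp.	CP026616	chromosomal_dif	TTTTG	ACTTCGCATAA	GGTGTA	TTATGTTAATT
Acinetobacter indicus	CP046392	pdif_in_chromosome	AGTCG	ACTTCGCATAA	CAGCCA	TTATGTTAAAT
Acinetobacter indicus	CP024620	pdif_in_chromosome	AGTGT	ACTTCGTATAA	TATCCA	TTATGTTAAAT
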