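is_name	accession	tsd	xerC	spacer	xerD
ISAjo2	CP010351(1)	AAAAA	GTTTCGTATAA	CAGCCA	TTATGTTAAAT
ISAjo2	CP010351(2)	CTCTC	GTTTCGTATAA	CAGCCA	TTATGTTAAAT
ISAjo2	CP010351(3)	TAAAAA	GATTCGTATAA	GGTGTA	TTATGTTAATT
ISAjo2-i	EF102240	ATCTC	GTTTCGTATAA	CAGCCA	TTATGTTAAAT
ISAjo2-i	CP078043	TTTTA	ATTTCGTATAA	GGTGCA	TTATGTTAATT
ISAba71	KY617771(1)	AACGC	ATTTCGTATAA	GGTGTA	TTATGTTAAAT
ISAba71	KY617771(2)	AGTGT	ACTTCGTATAA	CCGCCA	TTATGTTAAAT
ISAba71	CP084298(1)	TTGGG	AATTCGTATAA	CGTGTA	TTATGTTAATT
ISAba71	CP084298(2)	GTTCA	ACTTCGTATAA	CGTGTA	TTATGTTAATT
ISAba71	CP084298(3)	ACAGA	ATTTCGTATAA	CCACCA	TTATGTTAAAT
ISAba32	CP051211	TTTTG	GATTCGTATAA	GGTGTA	TTATGTTAATT
ISAba32	CP084302(1)	AGTGT	ACTTCGTATAA	CCGCCA	TTATGTTAAAT
ISAba32	CP084302(2)	AACAC	GTTTCGTATAA	GGTGTA	TTATGTTAATT
ISAba54	CP082952	ATCTC	GTTTCGCATAA	CAGCCA	TTATGTTAAAT
ISAba54	CP042365	CAGAG	ATTACGTATAA	CGTGTA	TTATGTTAATT
ISAba54	JX101647	CAAGC	ATTACGTATAA	CGTGTA	TTATGTTAATT
ISAso2	JX101647	CTCTC	GTTTCGTATAA	CAGCCA	TTATGTTAAAT
ISAso2	CP078043	ATCTC	GTTTCGCATAA	CAGCCA	TTATGTTAAAT
ISAso2	CP045127	AGTGT	ACTTCGTGTAA	TCGCCA	TTATGTTAAAT
ISApi2	CP033536	ATAGC	ATTTCGTATAA	GAGTTT	TTATGTTAAAT
ISApi2	CP051863	CTCTC	GTTTCGTATAA	CAGCCA	TTATGTTAAAT
ISApi2	MK134375	TTGGG	AATTCGTATAA	CGTGTA	TTATGTTAATT
ISAlw22	CP054822	AGGGC	CTTTCGTATAA	TGCCCA	TTATGTTAAAT
ISAlw22	CP032290(1)	AACGC	ATTTCGTATAA	GGTGTA	TTATGTTAATT
ISAlw22	CP032290(2)	TATAC	GTTTCGTATAA	GCTCTA	TTATGTTAAAT
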