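is_name	accession	tsd	xerC	spacer	xerD
ISKpn21	CP024290	CCTTT	AGTGCGCATAA	TGTATA	TTATGTTAAAT
ISKpn21	CP079726	GCATT	AGTGCGCTTAA	TGTACG	TTATGTTAAAT
ISKpn21	CP075891	ATACA	GGTGCGCATAA	CAAAGA	TTATGTTAAAT
ISKpn21	MN661402	GACTT	AGTGCGCATAA	TGTACG	TTATGTTAAAT
ISSen13	CP037875	CTT	AGTCGGTATAA	GATGGA	TTATGTTAAAT
ISSen13	KF362121	CTT	AGTGCGTATAA	GATTGA	TTATGTTAAAT
ISSen13	CP058810	CTT	AGTGCGTATAA	GACACA	TTATGTTAAAT
ISKpn65	LT994840	ATACA	GGTGCGCATAA	CAAAGA	TTATGTTAAAT
ISKpn65	CP001630	GAGAT	CTGTAAAGGCT	CAATGC	TTATGTCTAGT
ISKpn65	MK552108	AAGTT	TTGTAACAGCA	AAGTTG	TTATGTCCGCT
ISLad2	CP021463	GATG	AGTGCGCATAA	TCAGGA	TTATGTAAGAT
ISLad2	CP083321	CTTA	AGTGCGCATAA	GCTGGA	TTATGTAAGAT
ISLad2	KX710093	AGTA	AGTTGCTATAA	CGATAC	TTATGGAAAAT
ISBcen27	CP021069	ATCAA	AATGTCGATAA	TGTTGA	TTATGTCAAAT
ISBcen27	FR898703	ACAAA	AATGTTGATAA	TGTTGA	TTATGTCAAAT
ISBcen27	CP000960	ACAAA	AATATCGATAA	TCCGCA	TTATGTCAATC
ISRel10	CP001076	ACACC	AAATAGCATAA	TGCAAG	TTATGGAACTT
ISRel10	CP012125	ACACC	AAATAGCATAA	TCAAAG	TTATGGAACTT
ISRel10	CP020950	ACACC	AAATAGCATAA	TCAACG	TTATGGAACTT
ISMex6	CP001511	GTCGT	CGTTCGCATAA	GCGGTG	TTTTGACAAGA
ISMex6	CP001510	AAAGC	CGTTCGCATAA	GATATA	TTATGGAACGT
ISMex6	CP029173	CGAGC	TGTTCGCATAA	GATATC	TTATGGAACCT
ISRel26	CP013513	GTAAA	ATGTGGCGTAA	GACGCA	TTATGGAACAA
ISRel26	CP092434	ATAAC	ATATCGCATAA	TCTAAT	TTATGGAACCG
ISRel26	CP000134	ATAAC	ATGTCGCATAA	TCCAAT	TTATGGAACCG
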