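name	species	group	length_bp	tir	tsd_len	tnp_aa
ISAjo2	Acinetobacter johnsonii	cluster1	1482	19/24	5	441
ISAba71	Acinetobacter baumannii	cluster1	1482	20/24	5	441
ISAso2	Acinetobacter soli	cluster1	1482	20/24	5	457
ISApi2	Acinetobacter pittii	cluster1	1482	19/24	5	457
ISAba32	Acinetobacter baumannii	cluster2	1482	20/26	5	444
ISAba54	Acinetobacter baumannii	cluster2	1481	19/26	5	441
ISAlw22	Acinetobacter lwoffii	cluster2	1482	20/26	5	444
ISLad2	Leclercia adacarboxylata	short	1647	19/26	4	448
ISKpn65	Klebsiella pneumoniae	short	1980	16/26	5	452
ISRel10	Rhizobium etli	short	2528	15/25	5	473
ISRel26	Rhizobium etli	short	1634	17/24	5	457
ISMex6	Methylobacterium extorquens	short	1535	16/26	5	432
ISKpn21	Klebsiella pneumoniae	short	2278	25/25	5	467
ISSen13	Salmonella enterica	short	1542	17/28	3	456
ISBcen27	Burkholderia cenocepacia	short	1690	16/26	5	496
IS1202	Streptococcus pneumoniae	long	1747	18/23	27	465
ISCARN63	metagenomic	long	1387	21/26	17	414
ISCARN62	metagenomic	long	1398	16/24	16	432
ISTde1	Treponema denticola	long	1327	18/27	17	394
ISCARN53	metagenomic	long	1404	19/26	16	407
ISShha1	Shewanella halifaxens	long	1737	18/26	16	507
ISHahy13	Halanaerobium hydrogeniformans	long	1497	19/24	17	447
ISVbsp4	Vibrio sp.	long	1737	19/24	16	504
ISVisp7	Vibrio splendidus	long	1742	16/24	16	506
ISSeq2	Streptococcus equi	long	1544	21/25	28	465
ISRor8	Raoultella ornithinolytica	none	1472	17/28	0	465
ISEsa1	Enterobacter sakazakii	none	1609	15/22	0	439
ISCARN112	metagenomic	none	1468	23/29	0	428
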