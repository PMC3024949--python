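row_index	reported_site
1	CGATGCCGTTCAATCACCCT
2	GTTCAATCACCCT
3	GTTCAATCACCCT
4	CGATGCCGTTCAAT
5	CGATGCCGTTCAAT
6	CGATGCCGTTCAAT
7	CGATGCCGTTCAATCACCC
8	CGATGCCGTTCAAT
9	GCTACAACGAT
10	TCCGAGTGGG
11	TGAAATTTCTCAGTCTATTTGATA
12	GACTAGG
13	GGGGTGGCAC
14	TATATGGGGTGGCACCCGGG
15	GTGTCAGTGTACTCCCGCGAGC
16	CGCGAGCGTC
17	CCAATAG
18	GCTCAATCAAG
19	TGACGCTGCTCAATCAAGCT
20	AGGACATCCCGCATTTCACG
21	CGCTCATTGTTCTTAGTCGTGGTTTACAAGGACGGGGGAC
22	AACGGTGTTAACCCAA
23	GAAGTGAACGGTGTTAACCCAAGGCCACGA
24	ATTTTAT
31	GGAACCTTTAATATGTAAA
32	GCCCAATTGGCTGCGTAAGA
33	TGGAAGT
34	CCGAATTCCGGGTAGC
35	AGCGGGTGCATTC
36	AGTGTAAGCGTTTACGAACGC
37	GCTGATTAT
38	GTACCTTACGAC
39	GGTGCCGGCA
40	CTAGAGATGTAATTC
41	TCGCCCATCATATAG
42	GAGGGTATCAGC
48	TGGTCTTTTCCCGTTA
49	GTCTTTTCCCGTTAATT
50	CACCA
52	ACAGCGTCCT
53	GAATGAGCTCCCAGACGTCGA
54	CCACACGACATCTTTTATCGAGTCGCCTAGA
55	CATTCGACCCGAGATAGTGCCTC
56	GATCTGCAGGACAGTTAATGGCAAAAG
57	CTGCTTGGT
58	CATACTTCCGAATAGG
59	GGACTCACAC
60	CCGGGCGG
61	AATTGCCCTGTAA
63	GCCGGCACGTTTCTC
64	ACCACACCTG
65	ACTCACAC
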