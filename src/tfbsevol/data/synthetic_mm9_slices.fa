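>chr17:35640783
GAAATTGCATATTTTATAATATTGTTA
>chr17:35640977
CAAGATTCGAGAAGTGAACGGTGTTAACCCAAGGCCACGATGTTTGCCGCTCATTGTTCTTAGTCGTGGT
TTACAAGGACGGGGGACCACGCCGGAG
>chr17:35641421
AGATGCGCAGAGGACATCCCGCATTTCACGTGTTGTTCAT
>chr17:35641846
GGTCGAGACCTGACGCTGCTCAATCAAGCTTTACTGTCAG
>chr17:35641932
TTTTCCCATTCCAATAGTAAAGCGGAG
>chr17:35642023
GTCGATTACTGTGTCAGTGTACTCCCGCGAGCGTCCTCCTCGAAT
>chr17:35642094
AGCTCACCAATATATGGGGTGGCACCCGGGTTACAGATTC
>chr17:35642602
GGGTGCGATTGACTAGGTATTCCAAAG
>chr17:35642759
AGTACATATATGAAATTTCTCAGTCTATTTGATAGTAAAAAGGT
>chr17:35642867
CGGATCTAATTCCGAGTGGGAAAGAGTCAA
>chr17:35642919
AACACGACCAGCTACAACGATGCCGTTCAATCACCCTCTCGTACGAA
>chr3:34545064
GCTCGTAAATCTCCCGTGATCAGGCTATAGCG
>chr3:34545169
CCACAACTTCAGTGTAAGCGTTTACGAACGCTGATTATAAAATCTTTAGGTACCTTACGACCATTAACAT
T
>chr3:34545283
CCTGAGTTAAGGTGCCGGCATAATCCGTGG
>chr3:34547568
TCAAAGATCGCTAGAGATGTAATTCTAGGTCCCAT
>chr3:34548172
CGCTTCCCCATCGCCCATCATATAGAAAATATTGC
>chr3:34548476
AGACCCATAGAGCGGGTGCATTCCTCTCTCCCA
>chr3:34548858
AGGAACTGCTGGAACCTTTAATATGTAAACGGTACGTTC
>chr3:34552960
TATGAGCTTACCGAATTCCGGGTAGCGCTTGCCTAC
>chr3:34564278
TGTATCCATCGCCCAATTGGCTGCGTAAGAAGAACGGATTGGTTCCTGGAAGTCGAAGATAAA
>chr6:122652645
GTGCAATCCACTGCTTGGTCAAATCTGCG
>chr6:122653081
ATGTTTACTAACAGCGTCCTTTAACCGTCA
>chr6:122653125
TCCCACGGAAGAATGAGCTCCCAGACGTCGATGATATCGAT
>chr6:122653827
CGAACACGACCCGGGCGGGACAGTAGGA
>chr6:122655489
CAGCTTTATCAATTGCCCTGTAAAGTCCTAGTC
>chr6:122656925
CTTACATTCGCATTCGACCCGAGATAGTGCCTCGGATACTACG
>chr6:122657185
CGCGGACCGGGATCTGCAGGACAGTTAATGGCAAAAGACCTTTAATT
>chr6:122657301
GCGTGTGCCGCCACACGACATCTTTTATCGAGTCGCCTAGAGAAACGTGCCGGCCCCGTTCTAC
>chr6:122657398
CCCATCAGTTCACCACACCTGACCCCTACTGGTCTTTTCCCGTTAATTAATGCCCTTA
>chr6:122657520
AAGACAAATAGGACTCACACACCGCCCTATGGGAGCATACTTCCGAATAGGGTCTAACTAG
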