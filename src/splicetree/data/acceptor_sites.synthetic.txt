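CTTTTGTCTCCTTATTCCAGGTG
TTCGCGCTGTCCCCCCTCAGAGA
GTTAACTTCCAGTTTCCCAGGTG
CGTTTTTTACTTCGTTCCAGACC
TGCACTGAGTACTATTTCAGGAG
TTCTCTCTCTTTCTCTCCAGTAT
CTATATCCTTTCTTTACTAGACT
TCAACCTTCCTCTTTTTCAGAAA
TTAGTATCTCTTTCCTGCAGGAT
ATTTTTTCATTCTTCTATAGATA
GTTTGGTCTATCCTTTTCAGCAA
TGGATTTTGGCTCTTTCTAGGTT
CTTTTCGCTATTTTTCGTAGACT
GGCTACCTTATCTCAGGCAGAGA
TTTTTTCTCCTCTTTCTCAGATG
GTTGACTTTTCCTCTTTTAGGCC
CCTTCTCTTGTTGCTTACAGCCT
GCCTCTGATTGAGCCTGCAGAGC
TTTTTCCTTTGGTTTAACAGGAG
CCCCCCTCGTATCCTCCTAGCGG
CGTCCTCTCCCTAGTTCTAGGCC
TCCATCTATTTTTATGACAGCTC
CTCTTTTTTTCTTATTCCAGGCC
TCATTTGTTTCTCTTTTTAGGGA
ACTTTCTTCCCCTCGTTCAGGTA
TTTTACTCAGTAACTCATAGATG
TTGTCGCCTCTTCGTCACAGAAG
CGTAGGCTTTGCTCTTCCAGAGG
TTTTTCCGTGTTCCATGTAGCTG
CCTCTTCTTCTTTATCCCAGGTG
TTTACTGTTCCCTCATTTAGAGA
TTTTCTCACCAACACTTCAGCCC
ACGTTAATGGATTATCGCAGGCT
TTTTCTTCCCTTTTTCGCAGGCT
TCCTTTTTTTATTTTCTTAGGAC
GCTGCGTGAACCTCCCTCAGTGA
TTCTCCCCCACCCTTCGTAGAGA
TTCACGCTCCTTCTTCGTAGGGG
TTTTTTCCACTCCCTTCCAGGTT
TCGTCTTTCGCCTCCCACAGGTT
CCTCATATCTAACCGTACAGGCT
TATTCACTCTCCCTGCGCAGGAA
CAATTCCCTCGTTACTATAGTCT
ACCTTTTTTCTTGTCTCCAGGGT
CTCATCCTATATCTTTATAGGTG
CACGTTCCCACTCCTCCTAGCAA
GTTTCTTTCACCGTTTCTAGAAC
TCCTTCTCGTTTACCTTCAGTTG
GTGTTGCTCCCGCCCTTAAGAAC
TTTCTTTTACACTTACATAGGGC
TTCGCGTTTCCCGCCTTTAGCAA
TTCTTATATCTTACCTCCAGTGG
CATACGTCATTTGTTTTCAGGAC
TTTTTTTTTATTTCTTATAGCTT
CGCCCTTCTTTCCTACACAGGGG
TCCGTTCAATTCTACTTTAGACC
GCAGTTATTTCTTCTTCCAGGAA
TATTGTTCGTTCTTTTCTAGGAA
TTGGTCCGCCCACGTGCTAGCTG
CCATCGTTATTCCGCTGCAGGCT
CTTTTCTATCTTTTGTGCAGAGA
ACTTTCTCCATTCCTCTAAGTGA
TTCCCGTTTATGCTTCGCAGGGG
CCCCCCTATCACTCTCCTAGTAA
CACTCTCGACTCTTATTTAGGAA
CACTATTGCTCTTTCTTTAGATT
TATAAGCCGGTTCTTCCCAGATG
TTTCATGTCACGACCGCCAGAAC
TGTTAGTCGTTTTTCTTCAGGAC
TCTGGCCTTCTCTCTCCCAGGCT
TTTAATTCTTCCCCGCGTAGGGA
ATTTGCGCCGTGCTTTATAGGTC
CTACTTCTTCTTTGACGCAGGGC
CAGATTTTTTATTATTACAGAGT
TCCCTTTTTTTTTCTCGTAGGTT
CTTCAGTCTGTCTCTTGCAGGAT
CATATTTCGCTTCAGTCCAGAGA
CTCTTAACCCGCTTTTACAGGAC
TTCCTTTCTTTCGAGTACAGCTA
TCGTTTCTAATTGTGCCCAGGCG
CTTTGCATTTCTTTCTACAGGTG
GTTTTATGTCGTGTTTACAGAAG
TATTTTCTTTTTCTTCCTAGGTG
TCTCACTTTTCATTTCTGAGGAC
CTCACTCTTATTCCTCACAGAAA
ATTCTTTCTTTCACTTGCAGGAA
GCTTATCAGCTACTTCGCAGGTA
ACGTATTTCTGCATCTCTAGTGG
CTTTTCTTCTCGAATCACAGTTC
CCCATTTCCTAATTTCTCAGATC
TTTTCCGCCTGTTTTAACAGGAG
GCACTTCCTTATCTTTATAGAGA
CTCTCCGTCCCCCTTATCAGGAT
CATTTGGTATCTTGCTTTAGCCA
GGCTCAGCTTTCTCACACAGGAG
TACTAGCGTTTCCCTTTCAGTAC
TGATCTTTCACCCGGAGCAGGTG
CTCGTCTTCCCTGTTTATAGTGG
ATATTTTTTTATTTTTTCAGTTG
TCACCACGTTTTTTTTTCAGTTT
CACCCTTTTCCTCTTCCCAGGTG
TCTTACTTATTTCCCCCGAGGGT
CTTTCTCCTCGCATATCTAGCAA
TCTTTCATCCTATTTTTCAGAGC
TTTCCCTCTTCGTCTCTTAGGAA
ATCGCTATGTTACAGCTCAGGTA
TTCGGCTTCTTCTTTCGTAGTTA
CCGTTTCTTCTACTTCTTAGCTA
TCCTTTCATTACCGAGTCAGGAG
TCTTTTTCTTTCCTTTAAAGAGT
ACCTCTTCCCTCTCCTGCAGGTC
ACCAGCGTCCTCTCTTATAGAGG
TTACCCCTTATCTTTTACAGGTC
CTTTGCATTTGTCTTCGCAGATA
CCCTCTTCTATTTTTTCCAGAAC
TTGATGCTTTTTCCTTGCAGAGA
GCCTCTCCCACCCTTGTTAGGTC
GCTCCTGTAATATTTTCCAGAGG
CCCACTATCTAGTCTTTCAGATC
TTCTATTACCGCAGACTCAGCTG
TCTTTTCTTTCACTCTCCAGACT
TCCCCTCTTTGTGTCCTCAGGGT
TTTCCTTTTTCTCCTATCAGATA
TTTCCCTGCCATCTCTATAGTTC
CCTCGTTTTCCTATCGCCAGGGG
GCATATTTACCCCTTTACAGATC
CCCATTACCTAGTCATATAGAGG
CTTCTTCCACTTTTTTACAGATG
CCTATCTTGTACCATAACAGTCC
CTCTTGTTTCCCCTATCTAGTGC
TTTCCAATCATATCCCCCAGAGG
CTTTTGCCCTTTCGATACAGGAC
ACTTTCCCCCGTGCGTGCAGGCG
TCTCAGCCGCTTGTGCACAGATG
CACTTTTCTTTGCTGTTCAGATC
TCTCCGTCCTTTCTTCACAGGGG
TCCTTCTTGTCCGCACTAAGATC
GTGTCTTTTCTCTAGTCCAGATA
ACTTCCACTTGTTGATATAGGTT
CTAATTTTCAGCCTCTTCAGTCG
TACACTTATATAGTTTACAGGTT
TGCGTTTTCCCCTCCTGCAGGAA
GTCACCTCCTTAACTTACAGGAT
TGAATGATGTTTATATTCAGGGG
TACTCCTTCCGCGTATCCAGGCA
TTCCGAGTTTCTCTTCGCAGGTA
CCCATAATTTTTGTTCACAGGAA
CGGCATATTTTCTATTATAGAGT
TCTTCCTTTCTCTATTTCAGGAA
TCTCCCCTTCCGTGTCACAGCAC
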