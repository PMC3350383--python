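AACAGG
ACGCGG
ACTGGT
AGGAGG
AGGCAG
AGTTGT
AGTTTG
ATATGT
ATCGAG
ATTGGG
ATTGTT
ATTTTA
CATTGG
CCGGTT
CCGTCG
CGGTGG
CGGTTT
CTATCT
CTGGGG
CTTGTG
CTTTTT
GAGGGG
GAGTCC
GAGTTG
GATATG
GCAACT
GCCATA
GCGGGG
GCTCGA
GGAAGG
GGATTT
GGGAGG
GGGGGT
GGTAGC
GGTGCT
GGTTTC
GGTTTT
GTAGCT
GTCGTT
GTGAGA
GTGATC
GTGCCG
GTTATA
GTTGAC
GTTGTT
GTTTTC
TATCAG
TATCGT
TATGGC
TATTGG
TCATTA
TCATTT
TGAGAA
TGGGCG
TGGGGG
TGGTAC
TGGTGC
TGTCTT
TGTTGG
TTAGGG
TTAGTT
TTATGT
TTCAGA
TTCGAT
TTCGGA
TTGACC
TTGCTG
TTGGCA
TTGGCT
TTGTAT
TTGTCT
TTGTTG
TTTACG
TTTGCG
TTTTTT
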