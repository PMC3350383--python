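AACAGG
ACTGGT
AGTTGT
AGTTTG
ATATGT
ATCGAG
ATTGGG
ATTGTT
ATTTTA
CCGGTT
CCGTCG
CGGTGG
CGGTTT
CTGGGG
CTTGTG
CTTTTT
GAGGGG
GATATG
GCAACT
GCCATA
GCTCGA
GGATTT
GGTAGC
GGTTTC
GGTTTT
GTAGCT
GTCGTT
GTGAGA
GTGATC
GTGCCG
GTTGAC
GTTGTT
GTTTTC
TATCAG
TATCGT
TATGGC
TCATTA
TCATTT
TGAGAA
TGGGCG
TGGGGG
TGGTAC
TGGTGC
TTAGTT
TTATGT
TTCAGA
TTCGAT
TTGGCA
TTGTTG
TTTGCG
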