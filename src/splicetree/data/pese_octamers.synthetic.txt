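AAAAACAA
AAAAGATG
AAACCGGC
AAAGAGTA
AAAGGGGA
AACACGAA
AACGACTG
AAGCTGAG
AAGGCAAG
AAGGTGTG
AAGTGACA
ACAAGGGG
ACGAAGGC
ACGAGTGG
AGAATATG
AGACCAAA
AGAGAAAA
AGAGCAAA
AGCGAAGA
AGCGGATG
AGCGGGAA
AGGAATAT
AGGCGGGG
AGTGGGGT
AGTGGTAA
ATACAACG
CACGAAGA
CAGAGGGG
CAGGAAAG
CATCAAAG
CATTAAAG
CCGGGACC
CGAAGAAA
CGAGTGAG
CGAGTTCG
CGGAAGGA
CGGAGAGA
CGGCGATG
CGGGTGGA
CTAAACCA
GAAAAGAA
GAAAAGCG
GAAGAAGG
GAAGATTG
GAAGGAAG
GAAGGAGA
GAAGTGAG
GAATGAGA
GACGAAAG
GACTGAGT
GAGACGGA
GAGAGAGA
GAGGGAAG
GAGTGGGG
GCAGAGGA
GCGCAAGG
GCGGAGAA
GGAAAGGA
GGAAATAG
GGACGGAG
GGAGAAGA
GGAGGAAG
GGCGGCGG
GGGAACAA
GGGAGTAC
GGGAGTAG
GGGATGAG
GGGGATCG
GGGGGAGA
GGTCAATG
GTAGCGGG
GTCCGGGG
GTGGGGGC
GTTCAGAG
TAAAAGAG
TACTTAGC
TAGGATGG
TGGTGAGG
TGGTGGAG
TTGAAAAA
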