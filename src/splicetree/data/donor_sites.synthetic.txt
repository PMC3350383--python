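AAGGTAGGT
CAGGTAAGT
CAGGTAAGA
CGGGTAAGT
AATGTTGGA
CAGGTAAGA
CAGGTAAGC
CAGGTAGGC
CTGGTAAGT
CGAGCACGC
CAGGTAAGG
ATGGTTAGC
CTGGTAATA
AGGGTGAGT
GAGGTGAGT
CAGGTATGC
ACGGTAAGG
GAGGTGGGT
AAGGTAAGC
CAGGTCAGC
AAGGTGAGT
AAAGTGTCC
CGGGTAAAT
CATGTAATT
TGGGTGAGG
AAGGTGAGT
CGGGTAAGG
CAGGTATGA
CAGGTAAAT
AGGGTAGGT
GAGGTGTGT
CCGGTAGGC
CAGGTACGC
AAGGTACGT
CAGGTATCA
CTGGTAAGT
GAGGTGAAT
AAGGTAAGT
GAGGTAAGA
ATGGTGAGG
CAGGTAAGT
CCGGTAAGT
CAGGTAAGG
CAAGTTAGG
ACGGTAAGC
CAGGTGTGT
AAGGTAAGA
TTGGTGAGG
GCGGTGCGG
AATGTGTGG
GAGGTGAGG
TCGGTAGGC
AAGGTGCGA
CAGGTTAGC
CAGGTAATT
AGGGTAAGC
CATGTAAGA
TTCGTGAGC
TAGGTGAGC
TCAGTGAGG
AGGGTGGCG
CAGGTGAGT
CAGGTGAGT
CAGGTGACT
CAGGTAAGC
GCGGTGAGA
AAGGTAAGG
CAGGTGAGT
TTGGTTAAA
AAGGTGAGG
TAGGTGAGT
CTGGTAAGG
GAGGTGAGT
GAGGTAAGT
AAGGTAGGA
GCGGTACGT
CAGGTATGT
AAGGTGAGT
AAGGTACGC
GAGGTGAGT
GAGGTACGT
CTCGTGAGT
CTAGTAAGA
CAGGTACGT
AAGGTGAGC
AGGGTGAGG
CCGGTAAGC
CAGGTGCGT
AAGGTGAGT
AGGGTGAGT
ATGGTAAGT
CCGGTGGGA
GCTGTGAGG
GCGGCAAGC
CGGGTAAGG
GCTGTAAGT
AAGGTAGGT
CCGGTAAGT
CAGGTAAGG
TCGGTGTAT
CAAGTAAGC
ACAGTGAGC
ACGGTAGCT
CAAGTGAGC
AGGGTAAGT
CACGTAACG
AAGGTAAGG
CAGGTACGC
AAGGTGAGG
CATGTAAGT
CTGGTAAGA
CAGGTAAGG
CAGGTAAGA
AAGGTAGGC
GCAGTTAGC
AGTGTGTGG
AAGGTACAG
AAGGTAAGG
CAGGTACGT
AGGGTGATG
AAGGTGAGT
CAGGTGAGC
TTGGTGCGT
GAGGTAAGT
TAGGTAAGT
AAGGTAAGC
ATGGTGGGC
GAGGTGAGT
ACGGTGGGT
ACGGTAAGA
CGGGTGAGA
AAGGTGAGT
TAGGTAAGG
ACGGTGAGT
GAGGTAAAT
AAGGTGAGA
ATGGTGGGA
GAGGTAAGC
CGGGTGAGT
ACGGCATGT
CACGTGATT
TAGGTGAAT
CGGGTAAGC
CGGGTAAGT
AAGGTGAGG
CAGGTAAGA
ACGGTGAGA
TAGGTAGGA
AGGGTAAGA
CTGGTAACG
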