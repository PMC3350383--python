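AACCTGGG
AAGTAGAT
AATATTTG
ACATCCGG
ACGTGGTA
ACTCTGAA
ACTTACGT
AGACTTCC
AGCATCTT
AGTAGGCG
AGTGAGAG
ATACGTTT
ATGAGGTG
ATGTAGGC
ATGTCATG
CAATTAAT
CACTGCGG
CCGACTTG
CCGTCATT
CCTAAGCC
CGATTGGT
CGGAGGTC
CTATGTGC
CTTGAGTG
CTTGAGTT
CTTGTAGG
CTTTTGCT
GAAGTCAA
GAGGGCGG
GAGTTGGG
GATGAGTG
GATGTCTA
GCAACTGG
GCAATTGT
GCCTATTG
GCGCGTGT
GGACAGGG
GGCATTTT
GGGATGTT
GGGCTGTT
GGGGAAGG
GGGGGGGT
GGTCCTAT
GGTCGGTT
GGTCGTTT
GGTTGATG
GGTTTGTC
GTAAACGA
GTATGGAC
GTGTGGGT
GTTGAAGC
GTTGGAGT
GTTGTATT
TACGTTTG
TAGCGGGT
TAGGTTGA
TATGTTAT
TCACTCCT
TCACTCGA
TCAGGGGT
TCGAGTTT
TCGTGCAA
TCGTGTTG
TCGTTGCA
TCGTTTTG
TCTGATTC
TGCATAGG
TGCGCTCT
TGGATCGG
TGGCGGTA
TGGCGTGT
TGGGTCGG
TGGTTGTT
TGGTTTAT
TGTGCTGG
TGTGGTGG
TTACGTTT
TTGGATTG
TTGGGGCA
TTGGTTCA
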