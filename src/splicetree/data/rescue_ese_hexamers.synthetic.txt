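AAAACA
AAACGG
AACAAA
AAGAAA
AAGAAG
AAGGGA
AATGAC
ACAGAG
ACGAAG
ACGCTG
ACGGGA
ACGGGG
AGAAAG
AGAAGA
AGAAGC
AGAGAG
AGAGCA
AGAGGG
AGATGG
AGTAAA
ATGGGG
CAAGCG
CAGAAG
CATAGC
CGACGG
CGAGAG
CGAGCG
CGCGAA
CGCGAG
CGGCGC
GAAAAT
GAAAGA
GAACAT
GAAGAA
GAAGGA
GAGAGA
GAGATA
GAGCGG
GAGGAA
GAGGGA
GATAAG
GGAGAA
GGAGAC
GGAGAG
GGCAGA
GGCGAA
GGGAAA
GGGACA
GGGAGT
GGGGAA
TAAACG
TAAGAG
TAAGGA
TAGAGA
TAGTCA
TCCGAG
TGAAAA
TGGATA
TGGGGA
TGTGGA
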