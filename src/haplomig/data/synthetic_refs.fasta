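>sCOIA offset=401 frame=sCOI-synthetic synthetic
ACGTACAATCCGCAACCAACCCATAGTTAATGTATGTGCCTGCTGGTATGTGGAAGGATGACTTTCTCCA
AGCCAGGCCGGACTCTACCCCTCGGATGCGGTGTACCGTTTATAAGTACGTGCGCCCTGCTAACTGCAAA
GTCGCAAGTGCATTCGCTCTCCCGGTGGGCAAGGACGTGAGTGAGTCAGGAGTGAACGAGGCTACGCCTG
TGCCCGCGGTGTAGCTCTACATGAGTGGTGACCATATAAGTGCTCCTCTAAGATCGACTGGCCAGGGTTA
CAGAATAGTAACTGGAAGGT
>sCOIB offset=891 frame=sCOI-synthetic synthetic
CACTTATGGTGGAGGTTGCGTAGTGAAGCTTTTGAAAAGCTCTACAGGCGATGGTAGGTTTGGCGTTCAG
GGCTAAGCGCTTAGGAGGGGATGCTGGGGGGCAGTACCGCATTGGTCAGTCCACTAATTATCGCTTGCGT
TGAACACTTGTCCAATGTCTCCCACGCGTTCAACAAACTTTGCTTCCGTGACTGCTTCGTTGTGAGTTTA
CACAGCGATTTTCTAATTTCACGTTTCGCCGTGTACTCTATTAAGATGATTTACTAGAACATGTCAGGGC
TCGGTGTGACATAACTCTGCCTGATCTTCCGTTTAGAGATGCCATGGGTCTATAACCGGCCTCGGGACTT
GCTGTGGACTTACAACATGGGAGCACCGTTGTTATAAAGAAAAATTTAGGACGTAGGATCTTTCGGAGGC
AGTTCTTTGCCATTAAAGTGCGCCATATGGCCAGCCTCGAGTACAGTCGACAGTAAGCACTAAGGATACA
AGCACTTCATGTATCACGTGTAACTTGGTCGATATAGGCGAGTCACACTGTAACATTACAAGAGACATTA
GTGGCAG
>sTpiE offset=1 frame=sTpiE-synthetic synthetic
GGACGAGATACGTTCCAACAGTTACTCCCTAGCATCGGGGGGATAGTACTGCAGATGATTTTGTACGAAA
TGTACCTATGGGCGAATCAATTCTTTTCCTCCCCCAACGACCGACCCCCCACACTGTTCAAAACATCGCT
CCTGCTCACATACCAAGAAGCAGGGCAGTGTGTCCTCGAATCCAAAAGGAACTTCCACATTTCAAAGGTC
TAGGCACGTA
>sTpi140 offset=1 frame=sTpi140-synthetic synthetic
AATACTTCTAGTGAAGTGCTGTACTGCCGTGGTACATGGGCATCTACGTACCTTGCGTATACGGCGCCCT
ATTGTTATAATATGGCCTAAAACTACTGCCGTAGTAGTTCCAGGCAGCACTGTGGTGCGATGTGCGTCGC
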