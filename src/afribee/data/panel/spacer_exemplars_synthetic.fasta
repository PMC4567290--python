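>A synthetic stand-in exemplar for mitochondrial lineage A
ATTATAGACGTAGTATGAGCCAACTAGACGTGCGTAAGACCACACACCCACTCGGAGGCGGAATCCACGG
AAAGTACTCTACTAAGCCAGGCCCCTCCCTTGGTAACCCCGAGCATGATGCTCGCTACATTATCCCGAGT
CGACCTCGGTAGCTGGACATTTAATTTAGTCGTAACTAGCGATTGACGTGAGACTAAGCG
>C synthetic stand-in exemplar for mitochondrial lineage C
ATATCCCAACACGTTGGTGAAACGCAATCCGTCTTAGTTGTACAATCCGGTAGTCTATGGCGGTACGGCA
CCTCTGAATCCCCACACCAAATGAAGCGGTTTAGCTTGCGGTGTGGTATCACAGTCGCTTGCCCTGTAAG
TGTTAACTATATCTCTGTCCGGACGCCACGTCCTGGACCGAGTTTTGAACATTTCTAAAG
>M synthetic stand-in exemplar for mitochondrial lineage M
GTGGTACCTTTAGCGAGTGCGGACGAGCAACAGGACTCGGAATCAGCGAATCAGTTATCGAGTTACTAAC
TTAATGTATACTATGAAGCTCGTAGTTCGTTCGGAAAGCAATAACCAGCTAAGCGATTTAACTGGTGAAA
CCGTGTAGGAGATACTCTTGCGGCATAGCCCGATTTACCCTTGCCTCTATAAGAGCCATC
>O synthetic stand-in exemplar for mitochondrial lineage O
AAATCAAGCACGTGAGGGGGGTACGACAATACGCGGAATGTCTGACTCACCTGTCAGCTATATAGTTGGT
CCGAGCTAGAGGCTACGTCATAGCCCAGAGAAGTTCCCACACACGCTCTGTCGTCAGTTGGTCGTTTTAT
TGTATAAACTGCAGAGTGGGGTTGTGCTGATCACACAGCTATAAAGCAACGTTTTGGTGG
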