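>coi_reference_synthetic synthetic stand-in for an A. mellifera COI barcode fragment; T at the diagnostic site (European state)
CTTCAAAATCGGCGGTGGCACCCTCATACTCCTGGGGATCCAGTGGGTCTTTAATCGGGACCCCCCCTAT
TCGCGATTTAAGGCAGATTTTAACGCTGCCAGTCGGATCGGCGATGCCCGTAAGAATCACGAGGACACAA
TTTATGTGGAGTATGAAAGCTGGAATGACTCAAGTCGAGAAGGTTAAGTCATTACCGGGATACAGAGGAG
TCGTTAAGGGCGAGGAATCGCTGAATTCCAATGGGGTGGTGGGTAGGGGTGGTACTTCTAACCGTGAGTT
GAACAGAATGCGTTGTCGTAACAAATTTTTGGTTCAGGAATGGAGTGTATTAGTCCGCAACAGTGGCGCC
GGCAAGCATAGACTCACGACCTCTCGCAGTACCACTCTAAAGGGTATTTCGGAAGTGCGAGCCCAATATT
GGTGTTTGCTTCTTCGTTCAGCCGTCTAATACAAGTGACATGGACCCGGGCACTGTCCTTTCCCACACGC
ACGGGGCAAGAAAAACACATGGAACTCATAACCAGCACACGACCAGCTTTTTAGGCGTCTGTGATACGTG
GGGTCCGGATCGATTTATTGGGGCGCGGGCGCCGGACCAGCTTAATCTGTTTCCTCGGATAGTCTTACCC
AATTTTACACGCCGTTCTCGCGCCGATA
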