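>NAT2_amplicon chr8:18399625-18401720 synthetic stand-in sequence; site reference bases planted at catalog coordinates
TAGTTAGGTTGATGGTCCGTCATTATCTGTAATCTCCAATCGGTTCATAGTTTGAGCAACCTAGTTTAGA
AATCTAATGGATGGGTGTGCCGGTAAACCTAGGTCGAAGATGTTCCGTCCCGTACCGCATTCAAAAGTGT
CGCTGGGCCTACTGAACAACTGCTTGCGGGCAGCAAATGCTACGCTGAATCATCGCAGATACGCGAGCTC
GTTGAGCGTAGGCGTGGTAATAACAAGACGTGGCTTGATCGAGAGAGTGAAGCTCCGTGAAGGGAGCGCA
TCCAGGGGTTGCGTTGATGCAGGGTATTTAGCACCATACTTCACTAAAGAGCTTCAGTTTTCCTTAGGCC
CCAGAATTTCTGGTCGCATTACGTTAGCTAGAAGTACCTCATCTACCAGGTGCGGTCCCCCGTGCGACAC
AAACTTGACATCAACTATCCTCGGGACGATGGAGCTGATAGGGACTAGATATCCGTAGCGGTGGATATCA
CTAAACGGGGCCGACCGTTGTCAATTCAAAACACCCCCGGATGTACGACAGCACATGCGCTGGATCGTTT
GGGCAATCAGGTCGTGGCGCGGCTAGCCCCTATTAGCATATGGATGGCCTAGTAGAAAAAAGAGGGTATA
GCCGGTTGCCGTTTAGTCTTATCCCCACGCCCAAAGCACTCCCTTTAACAGGGGCGAGTCTCTCCGAGGC
TAGCTCAATTGGACAAGTATCTATGTACGTGTGCAAACAGACCTAAATAAATCCTGTTCCAGACGCGGCC
AGTCTACATCCACAGCGTCGGGTCCAATGTGTAAACATTGCGAGGTAGCAAATCACATCACCGGCTCCCT
AAGATTATTGCATTGCTAACGCCCAATACTCCACAGATCCAAGTAACACTCGTTAGGTATATCGATTGTA
ATTGACCATCTAACATACGCGGAAGCCAACACAACGTCCCGGTAAAAGAATCACACCCGTGGGTAACTTC
CTCGTTCGTGGGAAATCGGAACACCCATTGTCCGGAGACGCACGGTTGTGTCATGTTTTGTTCAGGTTTT
TTACCATTTTTCTTATTAGATTCGGCAATCAATTCAACCTTGTCAGTCTGGACTGGCTATGCACGATTCC
GAGGAGTCTCTTCGTTCAAAGCGCTTTCGCCCTTAAGGGGGCAGGGGTACTCATGTATCACAAAGCCTCG
TGGACTCGTGGTTCTAACCTGCACTTTAGTTGAATAATCTAATCTGTAATTATCGCTGACGACAGGGTAC
ATAGATGCATAGAAGCTGTAACTCTTGTTATGAAAGGAACGGGCATCCGATGCCAGCCGGCGATCCTGTT
TCGTCTCCCTTGGCTTTGGCAACCGTAGACTCAAGTTCAAGCACCTGGGGCCCCTTTAGGTTAGGCCAGC
GTCGGCTAACTGTTTGGCCGTGGGAGACTTCGCATTGTTATCTATACACTGGGGAAATCAGGACTACGCC
ATGTGATCCATGTTAAATTAGAGACATGCCCATTTTACGTGTTAAGATAGCCAATTGCCTGGGGGGATCA
GGAAGAACGTCTCTTAGTGCATTCCGTACCTCGTGGTCTCTTGGGTTGCCATATGACCCGCCCAGTCACG
AATTCTGTTTGGACTATCCCATACTGCGCCGCCGCTCCCAGTCAGGGCGCCGTACAATGATCTCTATCTA
TAAAATCGTCATTTTCTCTTTGAAGGGTCGCCCAGTCGAGCGCTCCATAATCGTAGATCGGCTGGATCGT
CGTTAATCGCATGCGGACGAAGAATCAGTTCCCTTAGCTTTTTAACAAGCGTGTCACCGACAAGACGACT
TTCTCGGGGCCGTCAGACATCGCACCGCAAGACTGCCTTCGCTTAGTTCTCATGAATCTTTTGCTATCCC
GTCAGTTTTAATCGCTTTGATCGTGTTTGTACGTGTTCCTCCACTGTATCCTGCGTAAGTTTAAAACTCT
CGTTCCGTATATGTAGAGCCTTCTACAAAAACTAAGAACACACATACGCGATAGTGCCACGTAGGCATTC
GGGAAGGTGACTGGATGTACGTTCATTACCGTTGATCGTGACTCCCCCGCCTCGCATGATACCGGG
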