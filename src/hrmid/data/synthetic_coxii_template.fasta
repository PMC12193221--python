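>synthetic P. misera COXII-like template|COXII|SYNTHETIC:1-691
GGAAATTCGTGGGTTACCTCCATACCTCCTCCAGTGACCTGACGACGAGTGGTAAACGCAGTGGGTCGGA
CCTATAGCGTGAGCGGCTGGCGCTAGTGATCTTACAAGATAGCACTGAGCCACCAAGCTCTGATAATAAA
CGATAGAAGGTAAGGCCGATTGGGAAGATAGTGCTCGACTTCCCTAAAGCCTAGATCCAACCCAGAGCAC
CGTCAGCTCTTATCACAAATCGTTCGTCAACTCCTTACGACCTAGAACCGGAACTAGAAGGACTTAGGCG
TACTTAAGATGCTAAAACCCCCATTCGTGCTTCTGAGTGGCATAATGCAGTTCCGGGATAGGGGGAGTTA
TCTCCCGGGGCTAGCCTTGTGGCCACGGTGCTATTTTTGCAAAACTCCGTGCGCATAGGTGGCGGACCCG
TGGTTGCTATTATAAAGGTCCTTATTCTAGTAGGCCTCCGGATCAGCGGGCAGCGCGATGGGGGTTGCAC
GATGTTGGTCTATGTACAAGTTGGGTGGTGGAACCCCTGGACGACTTAACGTTACCCCCCGGCCGATCGT
TGGAAGCGACCATCTGTAGACAGAATGCTTAAGTGTTTGCGGAGCTAATCACAGTTCTAAGGTTGACTGG
TAATTTGAAGTAGGAGGTCACAGGTTGCATTAACGGATGTGCTTCTCCCTGAAAGAGCCCT
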