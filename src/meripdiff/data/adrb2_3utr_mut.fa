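>Adrb2_3UTR_MUT printed mutant fragment, central A of each DRACH site replaced by T
TCTAGATAGTGTCCTGTCAAGGAGGGGTCTTAGAGAGTAGAAAGCCTGTATTACAGTGGCGAGTCATTTG
TACTACAGTTCCTTCCTTGGGAGTCAACGCTAAGGCTAGGCACAGTACCTTGACAGTTCACAAAGCCTTC
CATGCCTGGGGGATCCTCACACAGCAGTTCCTGTTCTCTCTCCTGCCCCAGCTGACAAGTGTTTGGCTCC
CCTGTGTAGTCCGTTCTGCCGTTGCTATTGCTAGAGTAGCCGTTCCCATAGGTTTTCGAAGAAGTCCTGC
GAAGGCACAGAAGCTCTTGAAAGGCAATCCTGAAATCTGGTCTCCGACAGTAGATAAGAGGATTGAAGGC
AGAGTTGACGTAGCCCAACCAGTTAAGGAGGATGTAAACTTCCTTAGGGATGAGGTTGTCCCTGATAACG
TGCACGATATTGACAATGAAGAAGGGCAGCCAGCAGAGGGTGAATGTGCCCATGATGATGCCTAAAGTCT
TGAGGGCTTTGTGCTCTTTCAAGCAGATCTTGGAGGTCCTTCGGAGTCCGTGGCCGCTCCGCCCATCCTG
CTCCACCTGGCTGAGGTTTTGGGCGTGGAATCTTCCTTCGCGGCCGC
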