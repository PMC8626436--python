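>Adrb2_3UTR_WT printed wild-type 3'UTR reporter fragment, four DRACH m6A sites
TCTAGATAGTGTCCTGTCAAGGAGGGGTCTTAGAGAGTAGAAAGCCTGTATTACAGTGGCGAGTCATTTG
TACTACAGTTCCTTCCTTGGGAGTCAACGCTAAGGCTAGGCACAGTACCTTGACAGTTCACAAAGCCTTC
CATGCCTGGGGGATCCTCACACAGCAGTTCCTGTTCTCTCTCCTGCCCCAGCTGACAAGTGTTTGGCTCC
CCTGTGTAGTCCGTTCTGCCGTTGCTATTGCTAGAGTAGCCGTTCCCATAGGTTTTCGAAGAAGACCTGC
GAAGGCACAGAAGCTCTTGAAAGGCAATCCTGAAATCTGGACTCCGACAGTAGATAAGAGGATTGAAGGC
AGAGTTGACGTAGCCCAACCAGTTAAGGAGGATGTAAACTTCCTTAGGGATGAGGTTGTCCCTGATAACG
TGCACGATATTGACAATGAAGAAGGGCAGCCAGCAGAGGGTGAATGTGCCCATGATGATGCCTAAAGTCT
TGAGGGCTTTGTGCTCTTTCAAGCAGAACTTGGAGGACCTTCGGAGTCCGTGGCCGCTCCGCCCATCCTG
CTCCACCTGGCTGAGGTTTTGGGCGTGGAATCTTCCTTCGCGGCCGC
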