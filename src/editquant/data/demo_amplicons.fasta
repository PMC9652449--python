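>demo_site1
AGGAGGGCGTTTTTTATCGTGAGTATCACGCATTGAGCCCCGGTCACCTGAACTGCCCCAAGGTTTCAGTGCCATTTAGGCAGAATCTATGTTATAGTATGGGTTTACCCCGTGTTACCCTGTTTACACGTACGCTAACACGGGGCGAAGGAGATTCCCCGAAGACGGCATAGTGATCATTTGCAATGAGTACTTCTTTC
>demo_site2
GTATGGACGCACACCTGTCTGTGCCTGAACCCAATGTTCATAAACTATAAGCAAGACTAGAGGGACTGCGAGTCGCATTTTCGATGAAGTGCGCAGGCCATACTCGGATGGCGGTTTTGGATGCAACAGTTGCTCTTGTACTGCATGTTCCATTACGCGTCCTTTGCGATCCGTGCACAGGTACTACACGTGCGAGAGGG
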