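>340|TRAC*01 IMGT|TRAC|C-REGION|TR|TRA|None|01
ATATCCAGAACCCTGACCCTGCCGTGTACCAGCTGAGAGGCTCTAAATCCAATGACACCTCTGTCTGCCT
ATTTACTGATTTTGATTCTGTAATGAATGTGTCACAAAGCAAGGATTCTGACGTGCATATCACAGACAAA
ACTGTGCTAGACATGAGGTCTATGGACTTTAAGAGCAACGGTGCTGTGGCCTGGAGCAACAAATCCGATT
TTGCATGTACAAGCGCCTTCAAGGACAGCGTTATTCCAGCAGACACCTTCTTCCCCGGCACAGAAAGTGT
CTGTGATGCCAACCTGGTTGAGAAAAGCTTTGAAACAGATATGAACCTAAACTTTCAAAACCTGTCAGTG
ATTGGGTTCCGAATCCTCCTCCTGAAAGTGGCCGGGTTTAATCTGCTCATGACGCTGCGGCTGTGGTCCA
GCTGA
>341|TRAC*02 TRAC_205_Ensembl_CDS|TRAC|C-REGION|TR|TRA|None|02
ATGAATGTGTCACAAAGCAAGGATTCTGACGTGCATATCACAGACAAAACTGTGCTAGACATGAGGTCTA
TGGACTTTAAGAGCAACGGTGCTGTGGCCTGGAGCAACAAATCCAATTTTGCATGTACAAGCGCCTTCAA
GGACAGCGTTATTCCAGCAGACACCTTCTTCCCCGGCACAGAAAGTGTCTGTGATGCCAACCTGGTTGAG
AAAAGCTTTGAAACAGATATGAACCTAAACTTTCAAAACCTGTCAGTGATTGGGTTCCGAATCCTCCTCC
TGAAAGTGGCCGGGTTTAATCTGCTCATGACGCTGCGGCTGTGGTCCAGCTGA
>342|TRAC*03 TRAC_201_Ensembl_CDS|TRAC|C-REGION|TR|TRA|None|03
ATGAATGTGTCACAAAGCAAGGATTCTGACGTGCATATCACAGACAAAACTGTGCTAGACATGAGGTCTA
TGGACTTTAAGAGCAACGGTGCTGTGGCCTGGAGCAACAAATCCAATTTTGCATGTACAAGCGCCTTCAA
GGACAGCGTTATTCCAGCAGACACCTTCTTCCCCGGCACAGAAAGTGTCTGTGATGCCAACCTGGTTGAG
AAAAGCTTTGAAACAGATATGAACCTAAACTTTCAAAACCTGTCAGTGATTGGGTTCCGAATCCTCCTCC
TGAAAGTGGCCGGGTTTAATCTGCTCATGACGCTGCGGCTGTGGTCCAGCTGA
>343|TRAC*04 TRAC_202_Ensembl_CDS|TRAC|C-REGION|TR|TRA|None|04
ATGAATGTGTCACAAAGCAAGGATTCTGACGTGCATATCACAGACAAAACTGTGCTAGACATGAGGTCTA
TGGACTTTAAGAGCAACGGTGCTGTGGCCTGGAGCAACAAATCCAATTTTGCATGTACAAGCGCCTTCAA
GGACAGCGTTATTCCAGCAGACACCTTCTTCCCCGGCACAGAAAGTGTCTGTGATGCCAACCTGGTTGAG
AAAAGCTTTGAAACAGATATGAACCTAAACTTTCAAAACCTGTCAGTGATTGGGTTCCGAATCCTCCTCC
TGAAAGTGGCCGGGTTTAATCTGCTCATGACGCTGCGGCTGTGGTCCAGCTGA
>344|TRAC*05 TRAC_203_Ensembl_CDS|TRAC|C-REGION|TR|TRA|None|05
ACTGGGGTAAACAACCTCTTCTTTGGGACTGGAACAAGACTCACCGTTCTTCCAGATATCCAGAACCCTG
ACCCTGCCGTGTACCAGCTGAGAGGCTCTAAATCCAATGACACCTCTGTCTGCCTATTTACTGATTTTGA
TTCTGTAATGAATGTGTCACAAAGCAAGGATTCTGACGTGCATATCACAGACAAAACTGTGCTAGACATG
AGGTCTATGGACTTTAAGAGCAACGGTGCTGTGGCCTGGAGCAACAAATCCAATTTTGCATGTACAAGCG
CCTTCAAGGACAGCGTTATTCCAGCAGACACCTTCTTCCCCGGCACAGAAAGTGTCTGTGATGCCAACCT
GGTTGAGAAAAGCTTTGAAACAGATATGAACCTAAACTTTCAAAACCTGTCAGTGATTGGGTTCCGAATC
CTCCTCCTGAAAGTGGCCGGGTTTAATCTGCTCATGACGCTGCGGCTGTGGTCCAGCTGA
>345|TRAC*06 TRAC_204_Ensembl_CDS|TRAC|C-REGION|TR|TRA|None|06
ATGAATGTGTCACAAAGCAAGGATTCTGACGTGCATATCACAGACAAAACTGTGCTAGACATGAGGTCTA
TGGACTTTAAGAGCAACGGTGCTGTGGCCTGGAGCAACAAATCCAATTTTGCATGTACAAGCGCCTTCAA
GGACAGCGTTATTCCAGCAGACACCTTCTTCCCCGGCACAGAAAGTGTCTGTGATGCCAACCTGGTTGAG
AAAAGCTTTGAAACAGATATGAACCTAAACTTTCAAAACCTGTCAGTGATTGGGTTCCGAATCCTCCTCC
TGAAAGTGGCCGGGTTTAATCTGCTCATGACGCTGCGGCTGTGGTCCAGCTGA
>346|TRBC1*01 NW_001114291|TRBC1|C-REGION|TR|TRB|None|01
AGGACCTGAAAAAGGTGTTCCCACCCAAGGTCGCTGTGTTTGAGCCATCAGAAGCAGAGATCTCCCACAC
CCAAAAGGCCACGCTGGTGTGCCTGGCCACAGGCTTCTACCCCGACCACGTGGAGCTGAGCTGGTGGGTG
AACGGGAAAGAGGTGCACAGTGGGGTCAGCACGGACCCACAGCCCCTCAAGGAGCAGCCCGCCCTCGAGG
ACTCCAGATACTGCCTGAGCAGCCGCCTGAGGGTCTCGGCCACCTTCTGGCACAACCCCCGCAACCACTT
CCGCTGCCAAGTCCAGTTCTATGGGCTCTCGGAGGATGACGAGTGGACCGAGGACAGGGACAAGCCCATC
ACCCAAAAGATCAGCGCCGAGGTCTGGGGTAGAGCAGACTGTGGCTTCACCTCGGTGTCCTACCAGCAAG
GGGTCCTGTCTGCCACCATCCTCTATGAGATCCTGCTGGGGAAGGCCACCCTGTATGCTGTGCTGGTCAG
TGCCCTCATGTTGATGGCCATGGTCAGAGGAAGGATTTC
>347|TRBC1*02 IMGT000073|TRBC1|C-REGION|TR|TRB|None|02
AGGACCTGAAAAAGGTGTTCCCACCCAAGGTCGCTGTGTTTGAGCCATCAGAAGCAGAGATCTCCCACAC
CCAAAAGGCCACGCTGGTGTGCCTGGCCACAGGCTTCTACCCCGACCACGTGGAGCTGAGCTGGTGGGTG
AACGGGAAAGAGGTGCACAGTGGGGTCAGCACGGACCCACAGCCCCTCAAGGAGCAGCCCGCCCTCGAGG
ACTCCAGATACTGCCTGAGCAGCCGCCTGAGGGTCTCAGCCACCTTCTGGCACAACCCCCGCAACCACTT
CCGCTGCCAAGTCCAGTTCTATGGGCTCTCGGAGGATGACGAGTGGACCAGGACAGGGACAAGCCCATCA
CCCAAAAGATCAGCGCCGAGGTCTGGGGTAGAGCAGACTGTGGCTTCACCTCAGTGTCCTACCAGCAAGG
GGTCCTGTCTGCCACCATCCTCTATGAGATCCTGCTGGGGAAGGCCTCCCTGTATGCTGTGCTGGTCAGT
GCCCTCATGTTGATGGCCATGGTCAAGAGGAAGGATTTC
>348|TRBC2*03 IMGT000073|TRBC2|C-REGION|TR|TRB|None|01
AGGACCTGAAAAAAGTGTTCCCACCCAAGGTCGCTGTGTTTGAGCCATCAGAAGCAGAGATCTCCCACAC
CCAAAAGGCCACGCTGGTGTGCCTGGCCACAGCTTCTACCCCGACCACGTGGAGTTGAGCTGGTGGGTGA
ACGGGAAAGAGGTGCACAGTGGGGTCAGCACGGACCCACAGCCCCTCAAGGAGCAGCCCACCCTCGAGGA
CTCCAGATACTGCCTGAGCAGCCGCCTGAGGGTCTCGGCCACCTTCTGGCACAACCCCCGCAACCACTTC
CGCTGCCAAGTCCAGTTCTATGGGCTCTCGGAGGATGACGAGTGGACCGAGGACAGGGACAAGCCCATCA
CCCAAAAGATCAGCGCTGAGGCCTGGGGTAGAGCAGACTGTGGCTTCACCTCTGAGTCTTACCAGCAAGG
GGTCCTGTCTGCCACCATCCTCTATGAGATCTTGCTAGGGAAGGCCACCTTGTATGCCGTGCTGGTCAGT
GCCCTCGTGCTGATGGCCATGGTCAAGAGAAAGGATTCC
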