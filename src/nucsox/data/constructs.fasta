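>Sox6-SHL0 255 bp 601 construct, Sox6 motif at the dyad
GCATGATTCTTAAGACCGAGTTCATCCCTTATGTGATGGACCCTATACGCGGCCGCCATCAGAATCCCGG
TGCCGAGGCCGCTCAATTGGTCGTAGACAGCTCTAGCACCGCTTAAACGCACGTAGGACAATGGAGGCGC
GTTTTAACCGCCAAGGGGATTACTCCCTAGTCTCCAGGCACGTGTCAGATATATACATCGATGTGCATGT
ATTGAACAGCGACCTTGCCGGTGCCAGTCGGATAGAATTCCGGAC
>Sox6-SHL2 255 bp 601 construct, Sox6 motif at SHL2
GCATGATTCTTAAGACCGAGTTCATCCCTTATGTGATGGACCCTATACGCGGCCGCCATCAGAATCCCGG
TGCCGAGGCCGCTCAATTGGTCGTAGACAGCTCTAGCACCGCTTAAACGCACGTACGCGCTGTCCCCCGC
GTTTTGGACAATGGAGGCATTACTCCCTAGTCTCCAGGCACGTGTCAGATATATACATCGATGTGCATGT
ATTGAACAGCGACCTTGCCGGTGCCAGTCGGATAGAATTCCGGAC
>Sox6-SHL4 255 bp 601 construct, Sox6 motif at SHL4
GCATGATTCTTAAGACCGAGTTCATCCCTTATGTGATGGACCCTATACGCGGCCGCCATCAGAATCCCGG
TGCCGAGGCCGCTCAATTGGTCGTAGACAGCTCTAGCACCGCTTAAACGCACGTACGCGCTGTCCCCCGC
GTTTTAACCGCCAAGGGGATTACTCCGGACAATGGAGGCACGTGTCAGATATATACATCGATGTGCATGT
ATTGAACAGCGACCTTGCCGGTGCCAGTCGGATAGAATTCCGGAC
>Sox6-SHL024 255 bp 601 construct, Sox6 motifs at dyad, SHL2 and SHL4
GCATGATTCTTAAGACCGAGTTCATCCCTTATGTGATGGACCCTATACGCGGCCGCCATCAGAATCCCGG
TGCCGAGGCCGCTCAATTGGTCGTAGACAGCTCTAGCACCGCTTAAACGCACGTAGGACAATGGAGGCGC
GTTTTGGACAATGGAGGCATTACTCCGGACAATGGAGGCACGTGTCAGATATATACATCGATGTGCATGT
ATTGAACAGCGACCTTGCCGGTGCCAGTCGGATAGAATTCCGGAC
>mutated-601-core triple-motif core sequence as printed (144 nt)
ATCAGAATCCCGGTGCCGAGGCCGCTCAATTGGTCGTAGACAGCTCTAGCACCGCTTAAACGCACGTAGG
ACAATGGAGGCGCGTTTTGGACAATGGAGGCATTACTCCGGACAATGGAGGCACGTGTCAGATATATACA
TCGA
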