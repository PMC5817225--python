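>B1_Alu_synthetic
CGTTATTTTGCGTCGACAATTTAACCATCTAACGGGCGTCCATCTTGGGTTATAAAGAGGTGTGCCATGTTAAGAGTGTATTTAGCAATATCTTAAAATGCGATGATAGGCTTCGGTCCACGAAGCAGGTGTTAAGTCGTTTGGTCAGCA
>B2_synthetic
TAACATTTTACATATAGCTTATTGGCCGATGCGTGACCGCAGGGCAGGCAACTGCTCAGTGATAGCTGCAAACTTAATTTGCGATTTTCGTAAAGGTGTTGACATTCGCCTCTGAGGCGAATACATTCCGTTCACACAAGGAGCTAAACT
>B4_synthetic
AGATCGCAAGAGCGGCTTGGCACCACGACATGAGTGGGCCTTTTTTTCAGAACCCATTATCGCGCGGCCTTCACGTATCGGTTTTCTTAGAACAGTCCTCACTTCAGTTTCTCTGTTGCATATATCGGGCAGAGGGCATACGAGGGGACG
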