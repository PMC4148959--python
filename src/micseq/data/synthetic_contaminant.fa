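>synthetic_contaminant_1 randomly generated stand-in for a viral contaminant (synthetic, not a real genome)
ACCGCCGGGTACTAGCGCCGGGGCGTCCGACCTTGCTCAATGACAAGTGACTTTCGCGAG
CGTAAACGGCTCAGGCCGGGTTTGAAGCATGGATAGCATAAACAAGTGGGAGAGTACGGT
AACATCACTACACGAGGTACACGAGGTTTAGCGGGCATACCACTGATATATTCACACGTC
CTGTCAATAGACGAATCAAGTCTCGTAGCCCACAATGAGTTAAAGGGGTTGATGTAAAGT
ATCCATAACCTTGTTGCGACTTCCCCTCGCCACGGCGAAAGATCCGCTTCCTCTCGCTCG
ACGGTTCCAGTAGATTTGTCGACAAGATTTCAGATGAGTGCCCGCTAGCATGGCCAATTC
GAAATTTGATCTAAGAACTTCGAAAGAATGAGTCACACATTTTTGTGACCAACCTCGTGC
ATACGGTCTATGAGATCAGGAGGCTTTGCCATGAGGCTGCTTCCATTCTAAATTAAGCTA
TCTGTAAGGAGGGCCCTAGGATCACCCCGTTGACGAGGTAGTCGTGATGTCGACCCCATA
ACTAATATCGAGTCGATTGACCTTTACGGGGGACCTCTTTATCTGCATTTCTGATAAAAG
CCACTAAGACTCTGTTCTGCCGTTCGACGATAGAGACTCAAGCTGTCATTGGGAGATAAT
GCACGTAACACTCCGGCTTCCTTAAAAAGTTCTCACGTCCAGTAGATATGGGGTCACCTG
AATATGTTAGCCGACCTCTTTTTCAGGCGACGAAGTTACAACTCTCAATGATGTGTCAGG
TAGGCCATGAATTCACGTATCAGAGGGAGAGCGATTGCTACGCGTTGCGTGCATAACCCT
TATCATGGGGGGGATCAGCCAACCCATTGGCTGATAGCCTGGAAGAGGGTTCGTAAGAAC
CCGGAGACAGAGAATCGAAGGTCGTACGAAGCATACCTCTCCAACGACTAGAGGAATGAC
AAAGGCATCTTTAGAACCAAGCATTCGAAAAGCAAACTTCTGATATATAGTTGCCCTCTG
TGGTAGGAATGCGTTTAAACCCACTAGTGACCGAGACTTGTTATAGAGTGGTAGAGCACT
AGACGACGCTACGCCGGAGAAGCGGTTGGACAGTTTACGGCAGATAGTGGGACGCCGGGT
CAACTAGTTACGGCAACTACCGCGTGCCGCGTCTAACAGCCTTAGTTGGTGTTAGGAATT
TCCTCTGAAAAAACACTGGGGGGCTCTGTATGATCCAGACAATAGACCTATTGCCGGCAC
GAATCCGAGCGTTAAAACTTGCAGAAATCCAAGTTAAGTTTCCGGTTTTTACTCTGCACT
GCCTACAGCTCGTTTCGATCTTCTATAAACAACGTCACAACCCCCTAAGGAACCCCTGAA
TACTGAGCTAAAGTAAGCAAAGCTGCTCCATGGGAGAAGCCGTAGTCATCTATTGTATTA
TTTGACGTCGCAAGCTGGAGATCGTACTAAAATAGTCCTGCCATGCTAGAAATATGTGGT
AGGGCGTAAGAACGGCCGGGACTCCTGTCGCCCACTAATGTAATTAAAGGTGAGCAACGC
ACACTGAAAACGCATGGGTTTTCACTGTTGAGCCTACAAAGGGATGCCGGTGCATATTTA
TTAGTATGCCACGGGTAACTCACGGCTCTTATAATTCACCCTCAACGTTCAAGAAGTGTA
GTTATGCATACATTCTTATGTTATCCCCGCGGGAGTTACGAGCGCGGGGTGTCTATTGCT
AAGTACAAGACACAGTCGTCGACTTGGGTGATATGTGGTTGTGTGCATCAAGATGTCCTG
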