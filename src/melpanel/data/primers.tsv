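amplicon	forward	reverse
CDKN2A exon 1α	CACCAGAGGGTGGGGCGGA	CAGGGCGTCGCCAGGAGGA
CDKN2A exon 1β	TCCCAGTCTGCAGTTAAGG	CGGGTTTACAACGACTTAGAC
CDKN2A exon 2	GGCGGTGAGGGGGCTCTACA	ACCGATTGGCGCGTGAGCTG
CDKN2A exon 3	GCCGGTAGGGACGGCAAGAG	AAAGCGGGGTGGGTTGTGGC
CDK4 codon24 (exon2)	GGATGCTGGTGGTGTTCTTT	TTATTTCCTCAGGGTCCCCA
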