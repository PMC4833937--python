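name	pattern	description
ABRE	ACGTG	abscisic acid responsive element (ACGT core)
AuxRR-core	GGTCCAT	auxin responsive element
Box-W1	TTGACC	fungal elicitor responsive element
ERE	ATTTCAAA	ethylene responsive element
GARE	TCTGTTG	gibberellin-responsive element
HSE	AGAANNTTCT	heat shock element
JERE	AGACCGCC	jasmonate and elicitor responsive element
LTR	CCGAAA	low temperature responsive element
MBS	CAACTG	MYB binding site (drought inducibility)
TC-rich	ATTTTCTTCA	defence and stress responsive element
W-box	TTGACC	wounding/pathogen responsive WRKY binding site
WUN-motif	AAATTTCCT	wound responsive element
TCA	CCATCTTTTT	salicylic acid responsive element
CGTCA-motif	CGTCA	MeJA responsive element
TGACG-motif	TGACG	MeJA responsive element
Py-rich	TTTCTTCTCT	5' UTR Py-rich stretch, high transcription level
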