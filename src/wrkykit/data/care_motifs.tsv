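name	consensus	category	description
TATA-box	TATAAA	essential	core promoter element around -30 of transcription start
CAAT-box	CCAAT	essential	common element in promoter and enhancer regions
5UTR-Py-rich-stretch	TTTCTTCTCT	enhancer	element conferring high transcription levels
Gap-box	CAAATGAARA	light	part of a light responsive element
AE-box	AGAAACAA	light	part of a module for light response
ATCT-motif	AATCTAATCC	light	part of a conserved DNA module involved in light responsiveness
Box-4	ATTAAT	light	part of a conserved DNA module involved in light responsiveness
G-box	CACGTG	light	light responsive element
AACA_motif	AACAAAC	tissue	involved in endosperm-specific negative expression
CCGTCC-box	CCGTCC	tissue	element related to meristem-specific activation
ABRE	TACGTG	hormone	abscisic acid responsiveness
P-box	CCTTTTG	hormone	gibberellin-responsive element
TATC-box	TATCCCA	hormone	gibberellin responsiveness
GARE-motif	TCTGTTG	hormone	gibberellin-responsive element
TCA-element	CCATCTTTTT	hormone	salicylic acid responsiveness
SARE	TTCGACCATCTT	hormone	salicylic acid responsive element
CGTCA-motif	CGTCA	hormone	MeJA responsiveness
TGACG-motif	TGACG	hormone	MeJA responsiveness
TGA-element	AACGAC	hormone	auxin-responsive element
AuxRR-core	GGTCCAT	hormone	auxin responsiveness
ELI-box3	AAACCAAT	hormone	elicitor/hormone responsive element
MBS	CAACTG	abiotic	MYB binding site involved in drought inducibility
DRE	RCCGAC	abiotic	dehydration, low temperature and salt stress responsiveness
LTR	CCGAAA	abiotic	low-temperature responsiveness
HSE	AAAAAATTTC	abiotic	heat stress responsiveness
WUN-motif	AAATTTCCT	abiotic	wound-responsive element
TC-rich-repeats	ATTTTCTTCA	abiotic	defense and stress responsiveness (canonical core of a variable-length element)
W-box	TTGACC	other	WRKY binding site
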