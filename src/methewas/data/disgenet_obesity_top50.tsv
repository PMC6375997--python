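gene_symbol	reliability_score
MC4R	0.79
LEPR	0.64
LEP	0.44
PPARG	0.44
FTO	0.40
ADRB3	0.34
ADRB2	0.33
UCP3	0.31
ADIPOQ	0.30
IL6	0.29
NPY1R	0.28
ENPP1	0.28
SH2B1	0.28
CARTPT	0.26
NPC1	0.25
LPL	0.25
POMC	0.25
HOXB5	0.24
PRKCH	0.24
PACS1	0.24
RMST	0.24
TNF	0.24
CNR1	0.23
INS	0.23
PCSK1	0.23
ESR1	0.23
MC3R	0.23
UCP2	0.22
IRS1	0.22
HSD11B1	0.22
SIRT1	0.21
F2	0.21
SIM1	0.21
AGRP	0.21
NPY5R	0.21
CYP2E1	0.20
ICAM1	0.20
CPE	0.20
SERPINA12	0.20
PMCH	0.20
LBP	0.20
ACSL1	0.20
GPX3	0.20
HK2	0.20
SIRT3	0.20
FOXO3	0.20
GLUL	0.20
HADH	0.20
TF	0.20
NEIL1	0.20
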