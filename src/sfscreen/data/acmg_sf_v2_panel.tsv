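symbol	moi	domain
BRCA1	AD	cancer predisposition
BRCA2	AD	cancer predisposition
TP53	AD	cancer predisposition
STK11	AD	cancer predisposition
MLH1	AD	cancer predisposition
MSH2	AD	cancer predisposition
MSH6	AD	cancer predisposition
PMS2	AD	cancer predisposition
APC	AD	cancer predisposition
MUTYH	AR	cancer predisposition
BMPR1A	AD	cancer predisposition
SMAD4	AD	cancer predisposition
VHL	AD	cancer predisposition
MEN1	AD	cancer predisposition
RET	AD	cancer predisposition
PTEN	AD	cancer predisposition
RB1	AD	cancer predisposition
SDHD	AD	cancer predisposition
SDHAF2	AD	cancer predisposition
SDHC	AD	cancer predisposition
SDHB	AD	cancer predisposition
TSC1	AD	cancer predisposition
TSC2	AD	cancer predisposition
WT1	AD	cancer predisposition
NF2	AD	cancer predisposition
COL3A1	AD	aortopathy and connective tissue disorders
FBN1	AD	aortopathy and connective tissue disorders
TGFBR1	AD	aortopathy and connective tissue disorders
TGFBR2	AD	aortopathy and connective tissue disorders
SMAD3	AD	aortopathy and connective tissue disorders
ACTA2	AD	aortopathy and connective tissue disorders
MYH11	AD	aortopathy and connective tissue disorders
MYBPC3	AD	cardiac disorders
MYH7	AD	cardiac disorders
TNNT2	AD	cardiac disorders
TNNI3	AD	cardiac disorders
TPM1	AD	cardiac disorders
MYL3	AD	cardiac disorders
ACTC1	AD	cardiac disorders
PRKAG2	AD	cardiac disorders
GLA	XL	Fabry disease
MYL2	AD	cardiac disorders
LMNA	AD	cardiac disorders
RYR2	AD	cardiac disorders
PKP2	AD	cardiac disorders
DSP	AD	cardiac disorders
DSC2	AD	cardiac disorders
TMEM43	AD	cardiac disorders
DSG2	AD	cardiac disorders
KCNQ1	AD	cardiac disorders
KCNH2	AD	cardiac disorders
SCN5A	AD	cardiac disorders
LDLR	SD	familial hypercholesterolemia
APOB	SD	familial hypercholesterolemia
PCSK9	SD	familial hypercholesterolemia
RYR1	AD	malignant hyperthermia
CACNA1S	AD	malignant hyperthermia
ATP7B	AR	Wilson disease
OTC	XL	ornithine transcarbamylase deficiency
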