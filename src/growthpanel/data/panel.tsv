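gene	category	inheritance	lof_mechanism
ACAN	SS disease	AD	1
FANCB	SS disease	XL	1
GDF5	SS disease	AD	1
GH1	SS disease	AD	1
GNAS	SS disease	AD	1
HRAS	SS disease	AD	0
IGF1R	SS disease	AD	1
IKBKG	SS disease	XL	0
LHX4	SS disease	AD	1
MMP13	SS disease	AD	1
NOG	SS disease	AD	1
NPR2	SS disease	AD	1
OBSL1	SS disease	AR	1
PTPN11	SS disease	AD	0
RUNX2	SS disease	AD	1
TP63	SS disease	AD	0
FANCA	SS disease	AR	1
FANCD2	SS disease	AR	1
CUL7	SS disease	AR	1
FANCM	SS disease	AR	1
IGFALS	SS disease	AR	1
SOS2	SS disease	AD	0
STAT5B	SS disease	AR	1
MAP2K1	SS disease	AD	0
CEP63	SS disease	AR	1
TRIP11	SS disease	AR	1
PRKCH	growth pathway	AD	0
LRP5	growth pathway	AD	1
COL1A1	growth pathway	AD	1
SOCS2	growth pathway	AD	1
CSNK2A2	growth pathway	AD	0
PEX2	growth pathway	AR	1
A2M	growth pathway	AD	0
RPS6KA1	growth pathway	AD	0
SOCS1	growth pathway	AD	1
BUB1B	growth pathway	AR	1
ELK1	growth pathway	AD	0
DGKE	growth pathway	AR	0
IGFBP1	growth pathway	AD	0
PTCH1	adult height	AD	1
ATXN3	adult height	AD	0
ZBTB38	adult height	AD	0
RNF135	adult height	AD	1
DOT1L	adult height	AD	0
TEAD3	adult height	AD	0
SDR16C5	adult height	AD	0
BCAS3	adult height	AD	0
EFEMP1	adult height	AD	0
PPARD	adult height	AD	0
NHEJ1	adult height	AR	1
NFKB1	adult height	AD	0
SH2B1	adult height	AD	0
LEPRE1	adult height	AR	1
MC4R	adult height	AD	0
DLEU7	adult height	AD	0
DNM3	adult height	AD	0
SF3B4	SS disease	AD	1
SOST	SS disease	AR	1
IGF1	SS disease	AR	1
SHOX	SS disease	AD	1
NDUFB3	SS disease	AR	1
TRPV4	SS disease	AD	0
GHR	SS disease	AR	1
GHRHR	SS disease	AR	1
GHSR	SS disease	AD	0
POU1F1	SS disease	AD	1
PROP1	SS disease	AR	1
HESX1	SS disease	AR	1
LHX3	SS disease	AR	1
SOX3	SS disease	XL	0
OTX2	SS disease	AD	1
GLI2	SS disease	AD	1
PTPN2	SS disease	AD	0
STAT3	SS disease	AD	0
JAK2	SS disease	AD	0
SOS1	SS disease	AD	0
RAF1	SS disease	AD	0
BRAF	SS disease	AD	0
KRAS	SS disease	AD	0
NRAS	SS disease	AD	0
MAP2K2	SS disease	AD	0
SHOC2	SS disease	AD	0
CBL	SS disease	AD	0
RIT1	SS disease	AD	0
LZTR1	SS disease	AR	0
NF1	SS disease	AD	1
SPRED1	SS disease	AD	1
COL2A1	SS disease	AD	1
COL10A1	SS disease	AD	1
COL11A1	SS disease	AD	1
COMP	SS disease	AD	0
MATN3	SS disease	AD	0
FGFR3	SS disease	AD	0
NPR3	SS disease	AR	1
NPPC	SS disease	AD	1
PTH1R	SS disease	AD	1
PTHLH	SS disease	AD	1
IHH	SS disease	AD	1
EVC	SS disease	AR	1
EVC2	SS disease	AR	1
DYNC2H1	SS disease	AR	1
PCNT	SS disease	AR	1
POC1A	SS disease	AR	1
CENPJ	SS disease	AR	1
CEP152	SS disease	AR	1
ORC1	SS disease	AR	1
ORC4	SS disease	AR	1
ORC6	SS disease	AR	1
CDT1	SS disease	AR	1
CDC6	SS disease	AR	1
ATR	SS disease	AR	1
NBN	SS disease	AR	1
BLM	SS disease	AR	1
WRN	SS disease	AR	1
RECQL4	SS disease	AR	1
LIG4	SS disease	AR	1
XRCC4	SS disease	AR	1
DDX11	SS disease	AR	1
SMARCAL1	SS disease	AR	1
SRCAP	SS disease	AD	1
ANKRD11	SS disease	AD	1
CREBBP	SS disease	AD	1
EP300	SS disease	AD	1
KMT2D	SS disease	AD	1
KDM6A	SS disease	XL	1
NIPBL	SS disease	AD	1
SMC1A	SS disease	XL	0
RAD21	SS disease	AD	1
HDAC8	SS disease	XL	1
ROR2	SS disease	AR	1
WNT5A	SS disease	AD	1
DVL1	SS disease	AD	0
SRY	SS disease	XL	0
IGF2	growth pathway	AD	1
IGFBP3	growth pathway	AD	0
IGFBP2	growth pathway	AD	0
IGFBP4	growth pathway	AD	0
IGFBP5	growth pathway	AD	0
IGFBP6	growth pathway	AD	0
PAPPA	growth pathway	AD	0
PAPPA2	growth pathway	AR	1
STAT5A	growth pathway	AD	0
IRS1	growth pathway	AD	0
PIK3R1	growth pathway	AD	0
AKT1	growth pathway	AD	0
AKT2	growth pathway	AD	0
RPS6KB1	growth pathway	AD	0
MTOR	growth pathway	AD	0
RICTOR	growth pathway	AD	0
RPTOR	growth pathway	AD	0
DEPTOR	growth pathway	AD	0
GRB10	growth pathway	AD	0
GRB2	growth pathway	AD	0
SHC1	growth pathway	AD	0
INSR	growth pathway	AD	1
INS	growth pathway	AD	1
IRS2	growth pathway	AD	0
PIK3CA	growth pathway	AD	0
PTEN	growth pathway	AD	1
TSC1	growth pathway	AD	1
TSC2	growth pathway	AD	1
RHEB	growth pathway	AD	0
EIF4E	growth pathway	AD	0
EIF4EBP1	growth pathway	AD	0
SOCS3	growth pathway	AD	0
CISH	growth pathway	AD	0
PTPN1	growth pathway	AD	0
PTPRF	growth pathway	AD	0
GHRH	growth pathway	AD	1
SST	growth pathway	AD	0
SSTR2	growth pathway	AD	0
SSTR5	growth pathway	AD	0
GHRL	growth pathway	AD	0
LEP	growth pathway	AR	1
LEPR	growth pathway	AR	1
POMC	growth pathway	AR	1
SIM1	growth pathway	AD	1
BDNF	growth pathway	AD	0
NTRK2	growth pathway	AD	0
THRA	growth pathway	AD	0
THRB	growth pathway	AD	0
TSHR	growth pathway	AR	0
DUOX2	growth pathway	AR	1
PDE4D	growth pathway	AD	0
PRKAR1A	growth pathway	AD	1
BMP2	growth pathway	AD	1
BMP4	growth pathway	AD	1
BMPR1A	growth pathway	AD	1
BMPR1B	growth pathway	AD	1
GDF11	growth pathway	AD	0
TGFB1	growth pathway	AD	0
TGFBR1	growth pathway	AD	0
TGFBR2	growth pathway	AD	0
SMAD4	growth pathway	AD	1
FBN1	growth pathway	AD	0
FGF21	growth pathway	AD	0
FGFR1	growth pathway	AD	1
FGFR2	growth pathway	AD	0
KL	growth pathway	AD	0
VDR	growth pathway	AR	0
HMGA1	adult height	AD	0
HMGA2	adult height	AD	1
HHIP	adult height	AD	0
LCORL	adult height	AD	0
NCAPG	adult height	AD	0
PLAG1	adult height	AD	0
DIS3L2	adult height	AR	1
CDK6	adult height	AD	0
ADGRG6	adult height	AD	0
ESR1	adult height	AD	0
CYP19A1	adult height	AR	1
SRD5A2	adult height	AR	0
AR	adult height	XL	0
TBX2	adult height	AD	1
TBX4	adult height	AD	1
TBX15	adult height	AD	0
SHOX2	adult height	AD	1
SALL4	adult height	AD	1
GPC3	adult height	XL	1
PHF6	adult height	XL	0
UBE2D2	adult height	AD	0
ZNF462	adult height	AD	1
CABLES1	adult height	AD	0
CHD7	adult height	AD	1
SOX9	adult height	AD	1
SOX5	adult height	AD	1
SOX6	adult height	AD	0
WNT4	adult height	AD	0
LRP6	adult height	AD	0
DKK1	adult height	AD	0
SFRP4	adult height	AD	1
GREM1	adult height	AD	0
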