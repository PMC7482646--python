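gene	category	direction	corrected_p
FANCA	SS disease	down	2.54E-17
FANCD2	SS disease	down	1.38E-08
CUL7	SS disease	down	5.61E-05
FANCM	SS disease	down	7.74E-05
IGFALS	SS disease	down	4.73E-04
SOS2	SS disease	up	1.01E-03
STAT5B	SS disease	down	1.34E-02
MAP2K1	SS disease	up	1.68E-02
CEP63	SS disease	up	1.88E-02
HRAS	SS disease	up	4.24E-02
PRKCH	growth pathway	down	1.68E-10
LRP5	growth pathway	up	2.34E-05
COL1A1	growth pathway	down	7.13E-05
SOCS2	growth pathway	up	9.82E-04
CSNK2A2	growth pathway	down	6.73E-03
A2M	growth pathway	down	1.19E-02
RPS6KA1	growth pathway	down	1.88E-02
SOCS1	growth pathway	up	1.88E-02
PEX2	growth pathway	down	2.11E-02
BUB1B	growth pathway	down	3.85E-02
PTCH1	adult height	down	3.47E-07
ATXN3	adult height	up	2.34E-05
ZBTB38	adult height	down	4.73E-04
RNF135	adult height	down	1.97E-03
DOT1L	adult height	up	2.97E-03
TEAD3	adult height	up	9.79E-03
SDR16C5	adult height	up	1.34E-02
BCAS3	adult height	down	1.88E-02
EFEMP1	adult height	down	3.61E-02
PPARD	adult height	up	4.24E-02
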