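gene	category	direction	corrected_p
NPR2	SS disease	down	7.22E-04
TRIP11	SS disease	down	1.55E-03
FANCM	SS disease	down	1.18E-02
CUL7	SS disease	down	1.60E-02
FANCA	SS disease	down	5.04E-02
BUB1B	growth pathway	down	1.59E-07
ELK1	growth pathway	down	5.18E-03
DGKE	growth pathway	up	9.01E-03
IGFBPI	growth pathway	down	4.63E-02
PEX2	growth pathway	down	4.63E-02
PTCH1	adult height	down	7.22E-04
NHEJ1	adult height	down	4.85E-03
TEAD3	adult height	up	7.08E-03
NFKB1	adult height	down	1.03E-02
SH2B1	adult height	up	1.03E-02
LEPRE1	adult height	down	2.95E-02
MC4R	adult height	down	5.04E-02
BCAS3	adult height	down	5.04E-02
DLEU7	adult height	down	5.04E-02
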