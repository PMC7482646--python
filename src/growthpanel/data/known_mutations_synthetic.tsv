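gene	hgvs_c	classification	source
ACAN	c.2023C > T(ENST_00000439576)	Pathogenic	lovd
ACAN	c.2149G > T(ENST_00000439576)	Pathogenic	lovd
FANCB	c.2452A > G(ENST_00000398334)	Pathogenic	clinvar
IGF1R	c.4009C > T(ENST_00000268035)	Pathogenic	clinvar
IGF1R	c.3595G > A(ENST_00000268035)	Pathogenic	clinvar
IGF1R	c.3433G > A(ENST_00000650285)	Pathogenic	clinvar
MMP13	c.1214A > G(ENST_00000260302)	Pathogenic	lovd
NPR2	c.2723T > C(ENST_00000342694)	Pathogenic	clinvar
NPR2	c.2720C > T(ENST_00000342694)	Pathogenic	clinvar
OBSL1	c.4005C > A(ENST_00000404537)	Pathogenic	lovd
PTPN11	c.179G > C(ENST_00000351677)	Pathogenic	clinvar
ACAN	rs373470699	VUS	ensembl
SF3B4	rs1553765674	VUS	ensembl
SOST	rs755773799	VUS	ensembl
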