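patient	gene	hgvs_c	protein	rs_id	consequence	classification	variant_status
P01	ACAN	c.2023C > T(ENST_00000439576)	ENSP00000271628.8:p.Gly328AlafsTer52		Nonsense	Pathogenic	Heterozygous
P02	ACAN	c.2149G > T(ENST_00000439576)	ENSP00000263726.2:p.Cys92Tyr		Nonsense	Pathogenic	Heterozygous
P03	FANCB	c.2452A > G(ENST_00000398334)	ENSP00000263726.2:p.Arg235Gln	rs200161949	Missense	Likely pathogenic	Homozygous
P04	GDF5	c.1465C > A(ENST_00000374372)	ENSP00000328181.4:p.Asp75Ala		Missense	Likely pathogenic	Heterozygous
P05	GH1	c.75T > G(ENST_00000323322)	ENSP00000312673.5:p.Ser25Arg		Missense	Likely pathogenic	Heterozygous
P06	GNAS	c. 2150 A > G(ENST_00000371100)	-		Missense	Likely pathogenic	Heterozygous
P07	GNAS	c.1581C > A(ENST_00000371100)	-		Missense	Likely pathogenic	Heterozygous
P08	HRAS	c.481C > A(ENST_00000451590)	ENSP00000363489.3:p.Gln489Lys		Missense	Likely pathogenic	Heterozygous
P09	IGF1R	c.4009C > T(ENST_00000268035)	ENSP00000354720.4:p.Glu183GlyfsTer11	rs141802822	Missense	Likely pathogenic	Heterozygous
P10	IGF1R	c.3595G > A(ENST_00000268035)	-	rs886044448	Missense	Likely pathogenic	Heterozygous
P11	IGF1R	c.3433G > A(ENST_00000650285)	ENSP00000302237.3:p.Ala174ProfsTer57	rs769418210	Missense	Likely pathogenic	Heterozygous
P12	IGF1R	c.1162G > A(ENST_00000650285)	ENSP00000302237.3:p.Ser284AlafsTer8		Missense	Likely pathogenic	Heterozygous
P13	IGF1R	c.4066G > A(ENST_00000650285)	ENSP00000302237.3:p.Ser463%3D		Missense	Likely pathogenic	Heterozygous
P14	IKBKG	c.161G > A(ENST_00000594239)	ENSP00000264731.3:p.Thr566Met	rs782813189	Missense	Likely pathogenic	Homozygous
P15	LHX4	c.704G > A(ENST_00000263726)	ENSP00000352514.5:p.Gly447Arg		Missense	Likely pathogenic	Heterozygous
P16	LHX4	c1121T > C(ENST_00000263726)	ENSP00000341083.2:p.Phe321%3D		Missense	Likely pathogenic	Heterozygous
P17	LHX4	c.275G > A(ENST_00000263726)	-		Missense	Likely pathogenic	Homozygous
P18	MMP13	c.1372C > G(ENST_00000260302)	ENSP00000260302.3:p.Tyr405Cys	-	Missense	Likely pathogenic	Heterozygous
P19	MMP13	c.1214A > G(ENST_00000260302)	-	rs190896822	Missense	Likely pathogenic	Heterozygous
P20	NOG	c.224A > C(ENST_00000332822)	ENSP00000326819.3:p.Arg818Gly	-	Missense	Likely pathogenic	Heterozygous
P21	NPR2	c.2723T > C(ENST_00000342694)	ENSP00000260302.3:p.Asp258%3D	rs369313283	Missense	Likely pathogenic	Heterozygous
P22	NPR2	c.2720C > T(ENST_00000342694)	ENSP00000260302.3:p.Lys170Thr	rs1311857509	Missense	Likely pathogenic	Heterozygous
P23	NPR2	c.2678T > C(ENST_00000342694)	ENSP00000323421.3:p.Leu1155ArgfsTer57	-	Missense	Likely pathogenic	Heterozygous
P24	OBSL1	c.4005C > A(ENST_00000404537)	ENSP00000340944.2:p.Gly60Ala	rs375716830	Missense	Likely pathogenic	Homozygous
P25	PTPN11	c.179G > C(ENST_00000351677)	ENSP00000341615.7:p.Arg675Ter	rs397507509	Missense	Likely pathogenic	Heterozygous
P26	RUNX2	c.1381G > C(ENST_00000371438)		rs765089321	Missense	Likely pathogenic	Heterozygous
P27	TP63	c.1697C > T(ENST_00000264731)		rs745687224	Missense	Likely pathogenic	Heterozygous
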