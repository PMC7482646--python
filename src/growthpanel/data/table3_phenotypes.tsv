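sample_id	sex	age_years	dysmorphism	variant_status	gene	standing_height_sds	sitting_height_sds	target_height_sds	bmi_sds	head_circumference_sds	birthweight_sds	birth_length_sds	igf1_sds	igfbp3_sds	als
P01	female	10.67	Short neck	Heterozygous	ACAN	-4.31		-2.29	0.33				-0.13	-0.97	15.0
P02	male	6.83	High palate	Heterozygous	ACAN	-4.02	-3.18	-2.15	-1.02	-0.95	-2.25		-2.41	-1.07	11.0
P03	male	9.67	Nil	X-linked, hemizygous	FANCB	-2.15		-1.2	0.73	-1.58	-0.33	-1.61	-1.57	-1.61	7.3
P04	male	13	Nil	Heterozygous	GDF5	-2.53	-3.22	-1.08	-0.55	-0.96	0.86	-0.02	-1.57	-2.18	11.0
P05	male	7.83	Brachydactyly	Heterozygous	GH1	-2.85		-1.72	-0.51		-1.06	-1.61	-1.34	-1.32	13.0
P06	male	5.75	Nil	Heterozygous	GNAS	-2.99		-1.86	-0.02		-1.08	-1.7	-3.94	-2.13	7.9
P07	male	7.42	Nil	Heterozygous	GNAS	-1.81	-1.2	-0.29	-0.56	-0.75	0.9	0.48	-1.8	-1.89
P08	female	9.92	Nil	Heterozygous	HRAS	-2.24		-2.46	0.4		-1.24	-1.72	-1.56	-1.25	12.0
P09	male	3.58	Nil	Heterozygous	IGF1R	-2.09	-1.9	-1.51	-0.52	-3.42	-0.41	-0.17	-1.65	0.11	10.0
P10	male	14.5	Nil	Heterozygous	IGF1R	-4.23	-4.66	-2.23	-0.73	-3.03	-1.44	-0.84	-0.37	-1.16	18.0
P11	male	10.83	Nil	Heterozygous	IGF1R	-3.06	-2.92		-0.9				-2.11	-2.08	9.4
P12	male	14.25	Nil	Heterozygous	IGF1R	-3	-3.56	-0.84	-0.45	-0.57	0.5	-0.02	-3.73	-3.02	11.0
P13	male	9.17	Nil	Heterozygous	IGF1R	-3.18		-2.51	0.51		-0.53		-2.57	-1.25	12.0
P14	male	7.83	Nil	Homozygous	IKBKG	-3.07	-4.38	-0.55	-0.64	-2.43	0.04	0.72	-2.63	-2.29	7.8
P15	male	9.92	Nil	Heterozygous	LHX4	-2.92			-0.94	-1.72	-0.64	-1.61	-3.13	-1.53	9.5
P16	male	7	Nil	Heterozygous	LHX4	-2.56		-1.94	-2.02		-0.32	-1.02	-2.46	-1.97	8.8
P17	male	4.33	Nil	Homozygous	LHX4	-3.95	-3.99	-1.37	-0.14	-2.3	-0.8	-0.52	-2.42	-2.46	8.1
P18	male	9.08	Nil	Heterozygous	MMP13	-2.78	-2.37	-1.28	-3.39	-3.53	-1.33	-1.52	-2.82	-2.36	8.6
P19	male	7	Nil	Heterozygous	MMP13	-2.7		-2.52	-1.15	-4.2	-0.28		0.41	-0.41
P20	male	4.92	Nil	Heterozygous	NOG	-3.01	-3.12	-1.46	-0.87	-1.8	-0.8	-0.76	-1.86	-2.12	4.9
P21	female	5.75	Large forehead, depressed nasal bridge	Heterozygous	NPR2	-4.12		-2.4	0.06	-3.22	0.21		-4.44	-3.69	3.2
P22	male	8.75	Nil	Heterozygous	NPR2	-2.88	-3.28	-1.86	1.05	-0.06	0.22	1.18	-2.97	-1.88	7.3
P23	male	5.33	Low-set ears	Heterozygous	NPR2	-2.15		-1.2	0.73	-1.58	-0.33	-1.61	-1.57	-1.61	7.3
P24	female	10.08	Nil	Homozygous	OBSL1	-2.47		0.11	0.04	-0.61	0.44	0.21	-3.08	-1.94	12.0
P25	male	7.75	R testis not palpable	Heterozygous	PTPN11	-2.83		-0.11	0.27	-2.42	-0.03		-2.95	-2.79	13.0
P26	male	11.08	Bilateral radial abnormalities	Heterozygous	RUNX2	-2.54			-0.32	-1.13			-1.73	-1.53	13.0
P27	male	12.83	Nil	Heterozygous	TP63	-4.31	-4.25	-1.72	-4.12	-3.91	-2.9		-3	-3.91	5.1
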