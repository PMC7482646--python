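characteristic	n	mean	sd	ci_low	ci_high	value
age_years	259	8.4	3.2	8.0	8.8
male_percent						61
preterm_count						41
birth_length_sds	214	-0.7	1.3	-0.9	-0.5
sga_weight_count						26
birthweight_sds	253	-0.7	1.2	-0.8	-0.5
sga_length_count						27
microcephalic_count						110
dysmorphic_count						38
parent_short_count						96
weight_sds	258	-2.5	1.2	-2.7	-2.4
bone_age_years	250	6.1	3.0	5.7	6.5
height_velocity_cm_y	199	5.0	1.5	4.7	5.2
sitting_height_sds	165	-2.2	2.4	-2.6	-1.8
standing_height_sds	255	-2.9	0.7	-3.0	-2.8
midparental_height_sds	248	-1.3	0.8	-1.4	-1.2
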