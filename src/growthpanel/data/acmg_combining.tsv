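outcome	very_strong	strong	moderate	supporting	benign_strong	benign_supporting	rule
Pathogenic	1	1	0	0	0	0	PVS1+PS
Pathogenic	1	0	1	0	0	0	PVS1+PM
Pathogenic	1	0	0	2	0	0	PVS1+2PP
Pathogenic	0	2	0	0	0	0	2PS
Pathogenic	0	1	3	0	0	0	PS+3PM
Pathogenic	0	1	2	2	0	0	PS+2PM+2PP
Pathogenic	0	1	1	4	0	0	PS+PM+4PP
Likely pathogenic	1	0	0	1	0	0	PVS1+PP
Likely pathogenic	0	1	1	0	0	0	PS+PM
Likely pathogenic	0	1	0	2	0	0	PS+2PP
Likely pathogenic	0	0	3	0	0	0	3PM
Likely pathogenic	0	0	2	2	0	0	2PM+2PP
Likely pathogenic	0	0	1	4	0	0	PM+4PP
Benign	0	0	0	0	2	0	2BS
Likely benign	0	0	0	0	1	1	BS+BP
Likely benign	0	0	0	0	0	2	2BP
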