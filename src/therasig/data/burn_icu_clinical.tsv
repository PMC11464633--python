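patient_id	session	age	sex	burn_type	severity	vas_pre	vas_post	hads_anxiety_first	hads_anxiety_last	hads_depression_first	hads_depression_last
01	1	36	Male	Thermal	1	0	0	9	4	7	2
01	2	36	Male	Thermal	1	7	4	9	4	7	2
02	1	20	Male	Thermal	1	3	0	9	8	3	2
02	2	20	Male	Thermal	1	4	6	9	8	3	2
03	1	65	Male	Electric	2	0	0	2	2	3	0
03	2	65	Male	Electric	2	0	0	2	2	3	0
04	1	29	Male	Thermal	1	2	0	7	6	7	1
04	2	29	Male	Thermal	1	8	7	7	6	7	1
05	1	18	Female	Thermal	1	3	2	11	9	6	9
05	2	18	Female	Thermal	1	0	1	11	9	6	9
06	1	19	Male	Thermal	1	0	0	7	1	4	1
06	2	19	Male	Thermal	1	0	0	7	1	4	1
07	1	58	Male	Electric	2	2	0	0	1	0	2
07	2	58	Male	Electric	2	0	0	0	1	0	2
08	1	28	Male	Thermal	1	1	0	2	1	0	0
08	2	28	Male	Thermal	1	4	0	2	1	0	0
09	1	29	Male	Electric	2	0	1	4		2
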