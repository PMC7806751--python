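sex	n	curvilinear_length_cm	tail_length_cm	body_area_cm2	tail_area_cm2	total_area_cm2
female	7	262	64	15320	3730	19050
male	6	310	66	16136	3435	19571
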