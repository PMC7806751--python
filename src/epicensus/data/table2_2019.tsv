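host_id	year	sample_label	pass_index	is_resample	area_cm2	species	category	skin_remnants
CCR19-01	2019	A	1	false	25	C. manati	+++	A
CCR19-01	2019	A	1	false	25	LT	+++	A
CCR19-01	2019	A	1	false	25	ST	+++	A
CCR19-01	2019	A-1	2	true	25	C. manati	+++	P
CCR19-01	2019	A-1	2	true	25	LT	0	P
CCR19-01	2019	A-1	2	true	25	ST	+++	P
CCR19-01	2019	A-2	3	true	25	C. manati	+++	P
CCR19-01	2019	A-2	3	true	25	LT	+++	P
CCR19-01	2019	A-2	3	true	25	ST	+++	P
CCR19-01	2019	A-3	4	true	25	C. manati	+++	P
CCR19-01	2019	A-3	4	true	25	LT	+++	P
CCR19-01	2019	A-3	4	true	25	ST	+++	P
CCR19-02	2019	A	1	false	25	C. manati	+++	P
CCR19-02	2019	A	1	false	25	LT	+++	P
CCR19-02	2019	A	1	false	25	ST	+++	P
CCR19-02	2019	A-1	2	true	25	C. manati	+++	P
CCR19-02	2019	A-1	2	true	25	LT	+++	P
CCR19-02	2019	A-1	2	true	25	ST	+++	P
CCR19-02	2019	A-2	3	true	25	C. manati	+++	P
CCR19-02	2019	A-2	3	true	25	LT	+++	P
CCR19-02	2019	A-2	3	true	25	ST	+++	P
CCR19-02	2019	A-3	4	true	25	C. manati	++	P
CCR19-02	2019	A-3	4	true	25	LT	++	P
CCR19-02	2019	A-3	4	true	25	ST	++	P
CCR19-02	2019	B	1	false	25	C. manati	+++	P
CCR19-02	2019	B	1	false	25	LT	+++	P
CCR19-02	2019	B	1	false	25	ST	+++	P
CCR19-02	2019	C	1	false	25	C. manati	+++	P
CCR19-02	2019	C	1	false	25	LT	+++	P
CCR19-02	2019	C	1	false	25	ST	+++	P
CCR19-02	2019	D	1	false	25	C. manati	+++	P
CCR19-02	2019	D	1	false	25	LT	+++	P
CCR19-02	2019	D	1	false	25	ST	+++	P
CCR19-03	2019	A	1	false	25	C. manati	0	P
CCR19-03	2019	A	1	false	25	LT	0	P
CCR19-03	2019	A	1	false	25	ST	0	P
CCR19-03	2019	B	1	false	25	C. manati	++	P
CCR19-03	2019	B	1	false	25	LT	++	P
CCR19-03	2019	B	1	false	25	ST	0	P
CCR19-03	2019	C	1	false	25	C. manati	0	P
CCR19-03	2019	C	1	false	25	LT	+	P
CCR19-03	2019	C	1	false	25	ST	0	P
CCR19-03	2019	D	1	false	25	C. manati	0	P
CCR19-03	2019	D	1	false	25	LT	0	P
CCR19-03	2019	D	1	false	25	ST	0	P
CCR19-04	2019	A	1	false	25	C. manati	0	A
CCR19-04	2019	A	1	false	25	LT	0	A
CCR19-04	2019	A	1	false	25	ST	+	A
CCR19-04	2019	A-1	2	true	25	C. manati	++	P
CCR19-04	2019	A-1	2	true	25	LT	++	P
CCR19-04	2019	A-1	2	true	25	ST	++	P
CCR19-04	2019	A-2	3	true	25	C. manati	++	P
CCR19-04	2019	A-2	3	true	25	LT	++	P
CCR19-04	2019	A-2	3	true	25	ST	++	P
CCR19-04	2019	A-3	4	true	25	C. manati	++	P
CCR19-04	2019	A-3	4	true	25	LT	++	P
CCR19-04	2019	A-3	4	true	25	ST	++	P
CCR19-05	2019	A	1	false	25	C. manati	0	P
CCR19-05	2019	A	1	false	25	LT	++	P
CCR19-05	2019	A	1	false	25	ST	++	P
CCR19-05	2019	A-1	2	true	25	C. manati	0	P
CCR19-05	2019	A-1	2	true	25	LT	++	P
CCR19-05	2019	A-1	2	true	25	ST	++	P
CCR19-05	2019	A-2	3	true	25	C. manati	++	P
CCR19-05	2019	A-2	3	true	25	LT	++	P
CCR19-05	2019	A-2	3	true	25	ST	++	P
CCR19-05	2019	A-3	4	true	25	C. manati	++	P
CCR19-05	2019	A-3	4	true	25	LT	++	P
CCR19-05	2019	A-3	4	true	25	ST	++	P
CCR19-06	2019	A	1	false	25	C. manati	++	A
CCR19-06	2019	A	1	false	25	LT	++	A
CCR19-06	2019	A	1	false	25	ST	0	A
CCR19-06	2019	A-1	2	true	25	C. manati	0	P
CCR19-06	2019	A-1	2	true	25	LT	++	P
CCR19-06	2019	A-1	2	true	25	ST	0	P
CCR19-06	2019	A-2	3	true	25	C. manati	++	P
CCR19-06	2019	A-2	3	true	25	LT	0	P
CCR19-06	2019	A-2	3	true	25	ST	0	P
CCR19-06	2019	A-3	4	true	25	C. manati	++	P
CCR19-06	2019	A-3	4	true	25	LT	++	P
CCR19-06	2019	A-3	4	true	25	ST	++	P
CCR19-07	2019	A	1	false	25	C. manati	0	P
CCR19-07	2019	A	1	false	25	LT	+	P
CCR19-07	2019	A	1	false	25	ST	+	P
CCR19-07	2019	A-1	2	true	25	C. manati	+++	P
CCR19-07	2019	A-1	2	true	25	LT	+++	P
CCR19-07	2019	A-1	2	true	25	ST	+++	P
CCR19-07	2019	A-2	3	true	25	C. manati	+++	P
CCR19-07	2019	A-2	3	true	25	LT	+++	P
CCR19-07	2019	A-2	3	true	25	ST	+++	P
CCR19-07	2019	A-3	4	true	25	C. manati	+++	P
CCR19-07	2019	A-3	4	true	25	LT	+++	P
CCR19-07	2019	A-3	4	true	25	ST	+++	P
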