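host_id	year	sample_label	pass_index	is_resample	area_cm2	species	category	skin_remnants
CCR18-19	2018	A	1	false	25	C. manati	+++	P
CCR18-19	2018	A	1	false	25	LT	+++	P
CCR18-19	2018	A	1	false	25	ST	+++	P
CCR18-19	2018	B	1	false	25	C. manati	+++	P
CCR18-19	2018	B	1	false	25	LT	+++	P
CCR18-19	2018	B	1	false	25	ST	+++	P
CCR18-19	2018	C	1	false	25	C. manati	0	P
CCR18-19	2018	C	1	false	25	LT	+++	P
CCR18-19	2018	C	1	false	25	ST	0	P
CCR18-19	2018	D	1	false	25	C. manati	+++	P
CCR18-19	2018	D	1	false	25	LT	+++	P
CCR18-19	2018	D	1	false	25	ST	+++	P
CCR18-19	2018	E	1	false	25	C. manati	0	P
CCR18-19	2018	E	1	false	25	LT	+++	P
CCR18-19	2018	E	1	false	25	ST	+++	P
CCR18-19	2018	F	1	false	25	C. manati	+++	P
CCR18-19	2018	F	1	false	25	LT	+++	P
CCR18-19	2018	F	1	false	25	ST	0	P
CCR18-20	2018	A-1	1	false	25	C. manati	0	A
CCR18-20	2018	A-1	1	false	25	LT	+++	A
CCR18-20	2018	A-1	1	false	25	ST	0	A
CCR18-20	2018	B-1	1	false	25	C. manati	+++	A
CCR18-20	2018	B-1	1	false	25	LT	+++	A
CCR18-20	2018	B-1	1	false	25	ST	+++	A
CCR18-20	2018	C-1	1	false	25	C. manati	0	A
CCR18-20	2018	C-1	1	false	25	LT	+++	A
CCR18-20	2018	C-1	1	false	25	ST	0	A
CCR18-20	2018	D-1	1	false	25	C. manati	0	A
CCR18-20	2018	D-1	1	false	25	LT	+++	A
CCR18-20	2018	D-1	1	false	25	ST	+++	A
CCR18-20	2018	A-2	2	true	25	C. manati	0	P
CCR18-20	2018	A-2	2	true	25	LT	+++	P
CCR18-20	2018	A-2	2	true	25	ST	0	P
CCR18-20	2018	B-2	2	true	25	C. manati	0	P
CCR18-20	2018	B-2	2	true	25	LT	+++	P
CCR18-20	2018	B-2	2	true	25	ST	0	P
CCR18-20	2018	C-2	2	true	25	C. manati	0	P
CCR18-20	2018	C-2	2	true	25	LT	+++	P
CCR18-20	2018	C-2	2	true	25	ST	0	P
CCR18-20	2018	D-2	2	true	25	C. manati	+++	P
CCR18-20	2018	D-2	2	true	25	LT	+++	P
CCR18-20	2018	D-2	2	true	25	ST	0	P
CCR18-21	2018	A	1	false	25	C. manati	0	A
CCR18-21	2018	A	1	false	25	LT	0	A
CCR18-21	2018	A	1	false	25	ST	0	A
CCR18-21	2018	B	1	false	25	C. manati	0	P
CCR18-21	2018	B	1	false	25	LT	+	P
CCR18-21	2018	B	1	false	25	ST	0	P
CCR18-21	2018	C	1	false	25	C. manati	0	A
CCR18-21	2018	C	1	false	25	LT	++	A
CCR18-21	2018	C	1	false	25	ST	++	A
CCR18-21	2018	D	1	false	25	C. manati	++	A
CCR18-21	2018	D	1	false	25	LT	++	A
CCR18-21	2018	D	1	false	25	ST	++	A
CCR18-21	2018	E	1	false	25	C. manati	++	P
CCR18-21	2018	E	1	false	25	LT	++	P
CCR18-21	2018	E	1	false	25	ST	++	P
CCR18-21	2018	F	1	false	25	C. manati	++	P
CCR18-21	2018	F	1	false	25	LT	++	P
CCR18-21	2018	F	1	false	25	ST	++	P
CCR18-22	2018	A	1	false	25	C. manati	0	A
CCR18-22	2018	A	1	false	25	LT	0	A
CCR18-22	2018	A	1	false	25	ST	0	A
CCR18-22	2018	B	1	false	25	C. manati	+	A
CCR18-22	2018	B	1	false	25	LT	+	A
CCR18-22	2018	B	1	false	25	ST	0	A
CCR18-22	2018	C	1	false	25	C. manati	0	P
CCR18-22	2018	C	1	false	25	LT	++	P
CCR18-22	2018	C	1	false	25	ST	++	P
CCR18-22	2018	D	1	false	25	C. manati	0	A
CCR18-22	2018	D	1	false	25	LT	++	A
CCR18-22	2018	D	1	false	25	ST	++	A
CCR18-22	2018	E	1	false	25	C. manati	++	P
CCR18-22	2018	E	1	false	25	LT	++	P
CCR18-22	2018	E	1	false	25	ST	++	P
CCR18-22	2018	F	1	false	25	C. manati	++	A
CCR18-22	2018	F	1	false	25	LT	++	A
CCR18-22	2018	F	1	false	25	ST	++	A
CCR18-23	2018	A	1	false	25	C. manati	+++	A
CCR18-23	2018	A	1	false	25	LT	+++	A
CCR18-23	2018	A	1	false	25	ST	+++	A
CCR18-23	2018	B	1	false	25	C. manati	+++	A
CCR18-23	2018	B	1	false	25	LT	+++	A
CCR18-23	2018	B	1	false	25	ST	+++	A
CCR18-23	2018	C	1	false	25	C. manati	0	A
CCR18-23	2018	C	1	false	25	LT	+++	A
CCR18-23	2018	C	1	false	25	ST	+++	A
CCR18-23	2018	D	1	false	25	C. manati	0	A
CCR18-23	2018	D	1	false	25	LT	+++	A
CCR18-23	2018	D	1	false	25	ST	+++	A
CCR18-23	2018	E	1	false	25	C. manati	+++	A
CCR18-23	2018	E	1	false	25	LT	+++	A
CCR18-23	2018	E	1	false	25	ST	+++	A
CCR18-24	2018	A	1	false	25	C. manati	+++	A
CCR18-24	2018	A	1	false	25	LT	+++	A
CCR18-24	2018	A	1	false	25	ST	+++	A
CCR18-24	2018	B	1	false	25	C. manati	+++	A
CCR18-24	2018	B	1	false	25	LT	+++	A
CCR18-24	2018	B	1	false	25	ST	+++	A
CCR18-24	2018	C	1	false	25	C. manati	+++	A
CCR18-24	2018	C	1	false	25	LT	+++	A
CCR18-24	2018	C	1	false	25	ST	+++	A
CCR18-24	2018	D	1	false	25	C. manati	+++	A
CCR18-24	2018	D	1	false	25	LT	+++	A
CCR18-24	2018	D	1	false	25	ST	+++	A
CCR18-24	2018	E	1	false	25	C. manati	+++	A
CCR18-24	2018	E	1	false	25	LT	+++	A
CCR18-24	2018	E	1	false	25	ST	+++	A
CCR18-24	2018	F	1	false	25	C. manati	+++	A
CCR18-24	2018	F	1	false	25	LT	+++	A
CCR18-24	2018	F	1	false	25	ST	+++	A
CCR18-25	2018	A	1	false	25	C. manati	+++	P
CCR18-25	2018	A	1	false	25	LT	+++	P
CCR18-25	2018	A	1	false	25	ST	+++	P
CCR18-25	2018	B	1	false	25	C. manati	+++	P
CCR18-25	2018	B	1	false	25	LT	+++	P
CCR18-25	2018	B	1	false	25	ST	+++	P
CCR18-25	2018	C	1	false	25	C. manati	+++	P
CCR18-25	2018	C	1	false	25	LT	+++	P
CCR18-25	2018	C	1	false	25	ST	+++	P
CCR18-25	2018	D	1	false	25	C. manati	+++	P
CCR18-25	2018	D	1	false	25	LT	0	P
CCR18-25	2018	D	1	false	25	ST	+++	P
CCR18-25	2018	E	1	false	25	C. manati	+++	P
CCR18-25	2018	E	1	false	25	LT	+++	P
CCR18-25	2018	E	1	false	25	ST	+++	P
CCR18-25	2018	F	1	false	25	C. manati	+++	P
CCR18-25	2018	F	1	false	25	LT	+++	P
CCR18-25	2018	F	1	false	25	ST	+++	P
CCR18-25	2018	G	1	false	25	C. manati	+++	P
CCR18-25	2018	G	1	false	25	LT	+++	P
CCR18-25	2018	G	1	false	25	ST	+++	P
CCR18-25	2018	H	1	false	25	C. manati	+++	P
CCR18-25	2018	H	1	false	25	LT	+++	P
CCR18-25	2018	H	1	false	25	ST	+++	P
CCR18-25	2018	I	1	false	25	C. manati	+++	P
CCR18-25	2018	I	1	false	25	LT	+++	P
CCR18-25	2018	I	1	false	25	ST	+++	P
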