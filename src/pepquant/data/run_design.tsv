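run_order	run_id	sample_id	age	sex	treatment	block	is_reference
1	Q52a	Q52	ed17	F	C	B1	1
2	Q65	Q65	ed17	M	E	B1	0
3	Q30	Q30	ed12	F	C	B1	0
4	Q64	Q64	ed17	F	E	B1	0
5	Q10	Q10	ed12	M	E	B1	0
6	Q27	Q27	ed12	M	C	B1	0
7	Q4	Q4	ed12	F	E	B1	0
8	Q52b	Q52	ed17	F	C	B1	1
9	Q3	Q3	ed12	M	E	B2	0
10	Q23	Q23	ed12	M	C	B2	0
11	Q79	Q79	ed17	M	E	B2	0
12	Q9	Q9	ed12	F	E	B2	0
13	Q48	Q48	ed17	M	C	B2	0
14	Q78	Q78	ed17	F	E	B2	0
15	Q26	Q26	ed12	F	C	B2	0
16	Q54	Q54	ed17	F	C	B2	0
17	Q52c	Q52	ed17	F	C	B2	1
18	Q12	Q12	ed12	M	E	B3	0
19	Q49	Q49	ed17	M	C	B3	0
20	Q57	Q57	ed17	F	C	B3	0
21	Q24	Q24	ed12	M	C	B3	0
22	Q19	Q19	ed12	F	C	B3	0
23	Q72	Q72	ed17	M	E	B3	0
24	Q80	Q80	ed17	F	E	B3	0
25	Q2	Q2	ed12	F	E	B3	0
26	Q52d	Q52	ed17	F	C	B3	1
27	Q66	Q66	ed17	M	E	B4	0
28	Q6	Q6	ed12	M	E	B4	0
29	Q74	Q74	ed17	F	E	B4	0
30	Q29	Q29	ed12	M	C	B4	0
31	Q21	Q21	ed12	F	C	B4	0
32	Q55	Q55	ed17	F	C	B4	0
33	Q51	Q51	ed17	M	C	B4	0
34	Q7	Q7	ed12	F	E	B4	0
35	Q52e	Q52	ed17	F	C	B4	1
36	Q1	Q1	ed12	M	E	B5	0
37	Q68	Q68	ed17	F	E	B5	0
38	Q56	Q56	ed17	M	C	B5	0
39	Q62	Q62	ed17	F	C	B5	0
40	Q22	Q22	ed12	F	C	B5	0
41	Q25	Q25	ed12	M	C	B5	0
42	Q52f	Q52	ed17	F	C	B5	1
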