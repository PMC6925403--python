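position	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
1	0	16	1	1	7	3	0	11	2	2	1	0	0	1	10	0	0	2	10	3
2	1	4	5	3	10	0	1	12	5	5	2	1	0	0	1	0	0	9	7	4
3	0	1	3	3	12	1	1	11	3	5	4	2	0	2	2	0	0	9	7	4
4	0	4	0	5	8	1	0	7	1	12	4	5	5	2	2	2	2	6	3	1
5	3	3	1	1	6	0	3	3	2	15	2	3	1	4	0	3	0	7	6	7
6	2	2	5	1	6	1	1	3	2	9	13	2	2	2	2	0	0	10	2	5
7	8	3	1	1	3	1	5	2	3	0	13	2	4	4	0	3	3	5	5	4
8	7	7	0	2	1	8	3	0	0	2	9	1	2	1	2	2	7	1	3	12
9	6	4	0	2	0	3	10	1	6	1	3	1	6	2	2	4	7	3	4	5
10	16	6	1	2	1	9	5	1	0	1	1	0	3	2	0	7	8	0	1	6
11	9	3	2	2	0	14	9	2	0	3	0	3	5	1	1	6	7	0	2	1
12	4	3	0	5	0	3	6	0	5	1	1	3	3	1	4	3	17	2	4	5
13	3	1	3	3	0	3	8	2	5	0	5	2	7	2	9	7	2	1	3	4
14	3	1	8	5	0	3	6	0	3	0	4	2	7	8	5	5	2	1	4	3
15	1	4	5	4	1	3	2	1	2	0	1	11	7	6	3	7	7	5	0	0
16	1	0	6	6	2	5	2	3	1	2	2	13	5	4	1	5	3	4	3	2
17	1	4	5	11	1	3	2	1	2	5	0	8	6	8	1	6	0	3	2	1
18	3	2	9	8	0	4	2	5	3	4	0	5	0	10	7	4	1	1	0	2
19	1	1	12	2	5	1	1	4	9	2	4	5	3	4	7	5	3	0	0	1
20	1	1	3	3	7	4	3	1	16	1	1	1	4	6	11	1	1	1	4	0
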