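# name: Shapiro-donor
# kind: base-frequency-percent
# width: 9
# note: synthetic consensus-frequency stand-in; 3 exonic + 6 intronic nt
pos	A	C	G	T
1	33	37	18	12
2	60	13	14	13
3	8	4	81	7
4	0	0	100	0
5	0	2	0	98
6	55	3	38	4
7	71	8	12	9
8	7	5	82	6
9	17	18	20	45
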