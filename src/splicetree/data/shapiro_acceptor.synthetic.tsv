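# name: Shapiro-acceptor
# kind: base-frequency-percent
# width: 14
# note: synthetic consensus-frequency stand-in; 12 intronic + 2 exonic nt
pos	A	C	G	T
1	9	31	12	48
2	12	31	9	48
3	10	31	11	48
4	11	31	10	48
5	8	31	13	48
6	10	31	11	48
7	11	31	10	48
8	7	37	8	48
9	24	29	21	26
10	4	64	1	31
11	100	0	0	0
12	0	0	100	0
13	28	14	47	11
14	30	20	25	25
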