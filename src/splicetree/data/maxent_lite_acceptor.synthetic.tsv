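# name: MaxEnt-lite-acceptor
# kind: positional-logodds
# width: 23
# note: synthetic positional log2-odds stand-in for the maximum-entropy acceptor score
pos	A	C	G	T
1	-1.3219	0.3103	-1.1844	0.9411
2	-1.1844	0.3103	-1.3219	0.9411
3	-1.4739	0.3103	-1.0589	0.9411
4	-1.0589	0.3103	-1.4739	0.9411
5	-1.3219	0.3103	-1.1844	0.9411
6	-1.6439	0.3103	-0.9434	0.9411
7	-1.1844	0.3103	-1.3219	0.9411
8	-1.3219	0.3103	-1.1844	0.9411
9	-1.4739	0.3103	-1.0589	0.9411
10	-1.0589	0.3103	-1.4739	0.9411
11	-1.3219	0.3103	-1.1844	0.9411
12	-1.1844	0.3103	-1.3219	0.9411
13	-1.6439	0.3103	-0.9434	0.9411
14	-1.3219	0.3103	-1.1844	0.9411
15	-1.1844	0.3103	-1.3219	0.9411
16	-1.8365	0.5656	-1.6439	0.9411
17	-0.0589	0.2141	-0.2515	0.0566
18	-2.6439	1.3561	-4.6439	0.3103
19	2.0000	-5.6439	-5.6439	-5.6439
20	-5.6439	-5.6439	2.0000	-5.6439
21	0.1635	-0.8365	0.9107	-1.1844
22	0.2630	-0.3219	0.0000	0.0000
23	0.0566	-0.0589	0.1110	-0.1203
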