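# name: MaxEnt-lite-donor
# kind: positional-logodds
# width: 9
# note: synthetic positional log2-odds stand-in for the maximum-entropy donor score
pos	A	C	G	T
1	0.4005	0.5656	-0.4739	-1.0589
2	1.2630	-0.9434	-0.8365	-0.9434
3	-1.6439	-2.6439	1.6960	-1.8365
4	-5.6439	-5.6439	2.0000	-5.6439
5	-5.6439	-3.6439	-5.6439	1.9709
6	1.1375	-3.0589	0.6041	-2.6439
7	1.5059	-1.6439	-1.0589	-1.4739
8	-1.8365	-2.3219	1.7137	-2.0589
9	-0.5564	-0.4739	-0.3219	0.8480
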