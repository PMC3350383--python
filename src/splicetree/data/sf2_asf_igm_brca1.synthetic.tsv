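# name: SF2/ASF(IgM,BRCA1)
# kind: pwm
# width: 7
# threshold: 1.867
# note: synthetic SR-protein weight-matrix stand-in
pos	A	C	G	T
1	-1.3690	1.4482	0.5889	-1.1724
2	-0.8455	0.5964	-0.8114	1.3170
3	0.6225	-1.4878	1.3660	-1.4475
4	1.3122	-1.1139	-1.2832	0.3679
5	1.2446	-1.5050	0.5931	-0.8057
6	0.4972	-0.8486	1.1114	-1.0593
7	1.0692	-1.0641	-1.1773	0.5009
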