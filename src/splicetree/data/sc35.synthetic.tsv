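# name: SC35
# kind: pwm
# width: 8
# threshold: 2.383
# note: synthetic SR-protein weight-matrix stand-in
pos	A	C	G	T
1	-1.1791	-0.9608	1.3915	0.5767
2	0.2527	-0.9779	1.1736	-1.5219
3	1.3676	-1.5167	0.6119	-1.0519
4	-1.1006	1.2561	-0.9010	0.5677
5	-1.1387	-1.1481	0.4432	1.1499
6	-1.2808	0.5945	-1.4141	1.0909
7	-0.9749	1.4455	-1.4261	0.2859
8	1.4356	-1.4289	-0.8583	0.4827
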