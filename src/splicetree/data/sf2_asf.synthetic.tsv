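# name: SF2/ASF
# kind: pwm
# width: 7
# threshold: 1.956
# note: synthetic SR-protein weight-matrix stand-in
pos	A	C	G	T
1	-1.5891	1.3550	-1.3805	0.6498
2	1.1244	-1.0384	0.6832	-0.8827
3	0.4987	-1.0350	1.3946	-0.9456
4	1.1148	0.5802	-1.2945	-0.8537
5	1.3583	-1.2677	-1.3801	0.3356
6	-1.0265	-0.8246	1.1226	0.2512
7	1.2343	0.5796	-0.8550	-0.8509
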