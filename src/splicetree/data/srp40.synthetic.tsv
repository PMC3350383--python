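# name: SRp40
# kind: pwm
# width: 7
# threshold: 2.67
# note: synthetic SR-protein weight-matrix stand-in
pos	A	C	G	T
1	1.1930	-1.4064	-1.2016	0.5448
2	0.2835	1.0770	-1.5377	-1.4126
3	1.3609	-1.2051	-1.3411	0.3940
4	0.2940	-0.9856	1.1324	-1.3980
5	-1.3735	-1.3762	1.2711	0.6926
6	-0.8379	1.3436	0.5752	-1.5322
7	1.0842	-1.3763	0.5304	-1.1105
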