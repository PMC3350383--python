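# name: SRp55
# kind: pwm
# width: 6
# threshold: 2.676
# note: synthetic SR-protein weight-matrix stand-in
pos	A	C	G	T
1	0.2799	-1.1034	-1.5354	1.2760
2	-1.1683	1.2528	0.5143	-1.1141
3	1.0585	0.4481	-1.2845	-1.5698
4	0.3140	1.1453	-1.4971	-1.5470
5	0.3084	-1.2343	1.3877	-0.9187
6	1.1883	0.4861	-1.2056	-1.5090
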