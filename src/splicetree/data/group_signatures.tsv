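group	class	n	ME3'ss	SF2/ASF-D	ME5'ss	FE	FESS-D	GC5'ss	SH3'ss	SIZE
A	authentic	30	H	H	-	-	-	-	-	-
B	authentic	1	H	L	L	H	-	-	-	-
C	authentic	42	H	L	H	-	L	L	-	-
D	authentic	2	H	L	H	-	H	-	-	L
E	authentic	2	H	L	H	-	L	H	H	-
a	cryptic	4	L	-	-	-	-	-	-	-
b	cryptic	5	H	L	L	L	-	-	-	-
c	cryptic	2	H	L	H	-	L	H	L	-
d	cryptic	4	H	L	H	-	H	-	-	H
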