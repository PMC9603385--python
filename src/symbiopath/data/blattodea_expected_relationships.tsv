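product	BBOR	BGER	BGIGA	BLAT	BPLAN	CPUbr	MADAR
Ala	O	O	O	O	O	O	O
Ammonia	B	B	B	B	B	B	B
Arg	B	B	B	B	B	C	C
Asn	H	H	H	H	H	H	H
Asp	O	O	O	O	O	O	O
B1	-	-	-	-	-	-	-
B12	-	-	-	-	-	-	-
B2	B	B	B	B	B	B	B
B3	-	-	-	-	-	-	-
B5	-	-	-	-	-	-	-
B6	B	B	B	B	B	B	B
B7	-	-	-	-	-	-	-
B9	C	C	C	C	C	-	-
Cys	O	O	O	O	O	O	O
Gln	H	H	H	H	H	H	H
Glu	O	O	O	O	O	O	O
Gly	H	H	H	H	H	H	H
His	B	B	B	B	B	B	B
Ile	B	B	B	B	B	-	-
K2	B	B	B	B	B	B	B
LA	O	O	O	O	O	O	O
Leu	B	B	B	B	B	-	-
Lys	B	B	B	B	B	B	B
Met	B	B	B	B	B	-	-
Phe	B	B	B	B	B	B	B
Pro	H	H	H	H	H	H	H
Protoheme	H	H	H	H	H	H	H
Ser	O	O	O	O	O	O	O
Thr	B	B	B	B	B	-	-
Trp	B	B	B	B	B	-	-
Tyr	O	O	O	O	O	O	O
Urea	H	H	H	H	H	H	H
Val	B	B	B	B	B	-	-
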