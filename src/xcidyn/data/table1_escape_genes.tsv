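#gene	strand	mb_start	ratio_star129	status_star129	ratio_cast	status_cast	ratio_129	status_129	region	validated	cluster
Kdm6a/Utx	+	17.7	-0.3	E	-0.4	E	-0.8	E	0	1	4
Utp14a	+	45.6	-0.3	E	-1.7	E	-0.8	E	0	0	4
Eda2r	-	94.6	-1.9	E	-2.0	E	-2.3	E	0	0	3
Ogt	+	98.8	0.2	E	-0.9	E	0.4	E	0	0	3
Xist	-	100.7	8.7	E	6.5	E	10.2	E	0	0	4
Ftx/B230206F22Rik	-	100.8	-1.7	E	-0.8	E	-1.3	E	0	0	3
5530601H04Rik	-	102.3	0.2	E	-0.2	E	-0.4	E	0	0	2
2610029G23Rik	+	102.3	-0.4	E	-0.6	E	-0.4	E	0	0	3
Kdm5c/Jarid1c	+	148.7	-1.1	E	-0.7	E	-1.7	E	0	0	3
Nkap	+	34.7	-0.6	E	-0.3	E	-8.2	S	0	0	3
Hcfc1	-	71.2	-2.5	E	-2.9	E		S	0	0	3
Vbp1	+	72.8	-2.3	E	-3.0	E		S	0	0	3
Jpx/2010000I03Rik/Enox	+	100.7	-1.1	E	-1.3	E		I	0	0
Chm	-	110.3	0.2	E	-2.9	E	-3.0	I	0	0	4
Gpm6b	+	162.8	-0.4	E	-0.9	E	-3.6	S	0	0
Ofd1	-	162.9	-3.2	E	-0.2	E	-7.5	S	0	0	3
Mecp2	-	71.3	-1.8	E		S	-2.3	E	0	0	2
Ercc6l	-	99.4	-0.4	E		S	-0.6	E	0	0	2
Ndufb11	-	20.2	-0.5	E		S		S	0	0
A230072C01Rik	+	20.5	-2.9	E		S		S	0	0	2
6720401G13Rik	-	48.0	-2.8	E		S	-5.4	S	0	0	1
Fmr1	+	65.9	-2.4	E		S		S	0	0	3
Trmt2b	-	130.8	-0.5	E		S	-3.9	S	0	0
Rbm41	-	136.5	-2.4	E		S	-5.8	S	0	0	1
Figf	+	160.9	-2.2	E	-3.8	S		S	0	0	4
Mmgt1	-	53.9		S	-0.5	E		S	0	0
Siah1b	-	160.5		S	-1.6	E	-5.4	S	0	0
Mid1	+	166.3	-4.9	S	-0.4	E	-7.1	S	0	0
Sox3	-	58.1		S	0.3	E		S	0	0
Taf1	+	98.7	-1.1	I	-2.9	I	-0.6	E	0	0
Gm5643/Hnrnpa1l2	+	138.7	-1.2	I	2.6	I	-1.6	E	0	0
Zrsr2	-	160.4		S	-5.9	S	-2.0	E	0	0
Gpkow	+	7.27	-2.4	E	-1.2	E	-8.4	S	1	1	4
Wdr45	+	7.30	-3.0	I	0.0	E		S	1	0
Tcfe3	+	7.34	-1.9	E	-0.8	E	-6.7	S	1	0	4
Gripap1	+	7.37	-1.1	E	-1.5	E	-6.3	S	1	1	4
Slc35a2	+	7.46	-1.6	I	1.3	E		S	1	0
Timm17b	+	7.48	-0.9	E	-1.1	E		S	1	0	4
Ftsj1/LOC100044636	-	7.83	-0.3	E	-1.2	E		S	1	1	4
Hdac6	-	7.52	-7.5	S	-1.6	E		S	1	0
Wdr13	-	7.71		S	-1.0	E		S	1	1
Rbm3	-	7.72	-6.4	S	-1.7	E	-5.8	S	1	1
2900002K06Rik	+	7.72		S	-0.2	E		S	1	1
Ebp	-	7.77		S	-2.6	E		S	1	0
Ddx3x/LOC100045923	+	12.86	-1.7	E	-0.9	E	-2.1	E	2	1	3
Med14	-	12.34	-0.5	E	-1.4	E	-7.3	S	2	1	3
Usp9x	+	12.65	-0.9	E	-1.3	E	-9.0	S	2	1	3
1810030O07Rik	-	12.25	1.3	E	-5.1	S	-5.9	S	2	1	3
Uba1	+	20.24	-0.4	E	-3.7	S	-0.9	E	3	1	3
Cdk16/Pctk1	+	20.27	-1.1	E		S	-0.4	E	3	1	3
Usp11	+	20.28	-0.5	E	-7.1	S	-8.2	S	3	1	3
Araf	+	20.43	-1.0	E		S		S	3	0	3
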