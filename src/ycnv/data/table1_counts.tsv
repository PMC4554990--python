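# Reference-cohort carrier counts for the ten CNV patterns that show
# haplogroup overrepresentation, in a cohort of 1506 haplogroup-assigned
# males.  Columns after "n" are carrier counts per pattern; ambiguous and
# unassigned individuals are excluded.
haplogroup	n	q-arm dupl + U3 del	P5 dupl	P4 dupl	P3 dupl	b1/b3 del (c3)	b2/b3 del (c35)	blue-grey dupl (c449)	blue-grey like dupl	gr/gr dupl + distal dupl	gr/gr del (c8)
C-M130	24	1	0	0	0	1	1	0	0	0	1
D-M174	6	0	0	0	0	0	0	0	0	0	5
E-M96	339	0	3	0	18	0	0	0	0	0	3
F-M89(xM1329)	10	0	0	2	0	0	0	0	0	0	0
G-M201	80	0	8	0	0	1	0	0	0	0	0
I-M170	40	0	0	0	0	0	0	0	0	0	1
J-M304	242	0	1	0	0	0	0	0	0	13	4
KLT-M9(xM526)	29	0	0	4	0	0	0	0	0	0	2
NO-M214(xM175)	40	0	0	0	0	0	27	4	7	0	0
O-M175	162	0	3	3	0	2	2	0	0	0	6
Q-M242	56	0	4	4	0	0	0	0	0	0	1
R-M207	478	0	0	0	1	0	0	0	0	0	4
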