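# Reference-cohort sample sizes and "any CNV" carrier counts per major
# haplogroup (1506 haplogroup-assigned males).
haplogroup	n	carriers
C-M130	24	5
D-M174	6	5
E-M96	339	44
F-M89(xM1329)	10	2
G-M201	80	12
I-M170	40	7
J-M304	242	30
KLT-M9(xM526)	29	7
NO-M214(xM175)	40	39
O-M175	162	25
Q-M242	56	11
R-M207	478	34
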