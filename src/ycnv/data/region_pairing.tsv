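# Palindrome/amplicon region definitions as pairs of bounding STS markers.
# A region spans from its left marker's start to its right marker's stop
# (1-based closed; marker interiors inclusive). Overlaps between adjacent
# regions sharing a bounding marker are intentional.
# region_class: palindrome | amplicon | inverted_repeat | spacer
name	left_marker	right_marker	region_class
PCDH11Y-up	sY_PC_a	sY_PC_b	spacer
AMELY-TBL1Y	sY_AM_a	sY_AM_b	spacer
NLGN4Y-up	sY_NL_a	sY_NL_b	spacer
AZFa-q	sY83	sY1318	spacer
USP9Y-3p	sY_U9_a	sY_U9_b	spacer
P7	sY1312	sY1304	palindrome
P6	sY1275	sY1276	palindrome
preP5	sY_pre5a	sY_pre5b	spacer
P5	sY1264	sY1283	palindrome
P4	sY1283	sY1277	palindrome
postP4	sY_post4a	sY_post4b	spacer
IR2	sY1315	sY1259	inverted_repeat
U1	sY141	sY142	spacer
P3	sY1247	sY1191	palindrome
U3	sY1191	sY1192	spacer
gr1	sY1291	sY1125	amplicon
b3	sY1125	sY1054	amplicon
Y1	sY1054	sY1206	amplicon
g1	g1_a	g1_b	amplicon
r1	r1_a	r1_b	amplicon
r2	r2_a	r2_b	amplicon
g2	BPY2_a	BPY2_b	amplicon
r3	sY254	DAZ3	amplicon
r4	DAZ4a	DAZ4b	amplicon
Y2	sY1206d	sY1054d	amplicon
b4	sY1054e	sY1125d	amplicon
g4	g4_a	g4_b	amplicon
gr2	sY1054f	sY1201	amplicon
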