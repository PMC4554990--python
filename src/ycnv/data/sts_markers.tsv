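# STS marker coordinates (chrY, 1-based closed intervals, hg19-style synthetic fixture).
# Columns: name, start, stop. Marker interiors are included in the regions they bound.
name	start	stop
sY_PC_a	4654108	4654608
sY_PC_b	4801601	4802101
sY_AM_a	6736000	6736500
sY_AM_b	6895715	6896215
sY_NL_a	13800000	13800500
sY_NL_b	13989500	13990000
sY83	14448577	14449077
sY1318	15230045	15230545
sY_U9_a	14939249	14939749
sY_U9_b	14973960	14974460
sY1312	15980000	15980500
sY1304	16109500	16110000
sY1275	18279605	18280105
sY1276	18842647	18843147
sY_pre5a	19100000	19100500
sY_pre5b	19499500	19500000
sY1264	19750000	19750500
sY1283	20450000	20450500
sY1277	21639500	21640000
sY_post4a	21900000	21900500
sY_post4b	22299500	22300000
sY1315	22450000	22450500
sY1259	22749500	22750000
sY141	22900000	22900500
sY142	23249500	23250000
sY1247	23400000	23400500
sY1191	24349500	24350000
sY1192	24649500	24650000
sY1291	24800000	24800500
sY1125	25299500	25300000
sY1054	25799500	25800000
sY1206	26199500	26200000
g1_a	26220000	26220500
g1_b	26223500	26224000
r1_a	26240000	26240500
r1_b	26243500	26244000
r2_a	26260000	26260500
r2_b	26263500	26264000
BPY2_a	26350000	26350500
BPY2_b	26599500	26600000
sY254	26700000	26700500
DAZ3	26949500	26950000
DAZ4a	27050000	27050500
DAZ4b	27299500	27300000
sY1206d	27400000	27400500
sY1054d	27699500	27700000
sY1054e	27800000	27800500
sY1125d	28199500	28200000
g4_a	28220000	28220500
g4_b	28223500	28224000
sY1054f	28300000	28300500
sY1201	28749500	28750000
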