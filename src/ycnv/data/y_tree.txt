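# Y-chromosome haplogroup tree fixture (synthetic panel).
#
# Format: indentation of two spaces per level gives the hierarchy; each line
# is "<node-name> <snp-spec> ...".  Defining SNPs are listed
# as id:ancestral>derived.  The panel covers the 12 major clades used for
# backmerging plus the internal nodes (DE-M145, GHIJKLT-F1329, IJ-M429,
# K-M526, P-P295) that arise when array panels lack downstream markers.
# 91 phylogenetically placed SNPs in total.
Root
  C-M130 M130:C>T M216:C>T P184:G>A P255:T>C P260:A>G RPS4Y711:C>T
  DE-M145 M145:A>G M203:C>A P144:G>T P153:A>C P165:T>C
    D-M174 M174:T>C P47:G>A M226:A>G M55:A>T M57:G>C JST022457:C>T P99:G>C
    E-M96 M96:G>C P29:A>G P150:C>T P152:G>A P154:T>A P162:A>C M40:C>A SRY4064:G>A
  F-M89 M89:C>T M213:T>C P14:C>G P133:A>G P134:G>A P135:C>A
    GHIJKLT-F1329 F1329:G>A M578:C>T P316:A>G
      G-M201 M201:G>T P257:A>G L116:C>T L154:G>A U21:T>C
      IJ-M429 M429:T>A P123:G>A P125:C>T P126:A>C
        I-M170 M170:A>C M258:T>C P19:G>A P38:C>A P212:T>G U179:G>T L41:A>G P30:C>T
        J-M304 M304:A>C P209:G>A L60:T>C F12f2:C>G L134:G>T
      KLT-M9 M9:C>G L15:A>G L16:G>A
        K-M526 M526:A>C P331:G>A P326:C>T
          NO-M214 M214:T>C P188:A>G P192:C>T P193:G>A P194:T>A P195:C>A
            O-M175 M175:A>T P186:C>T P191:G>C P196:T>G M1354:C>A
          P-P295 P295:C>T P27:G>A R92R7:A>G
            Q-M242 M242:C>T P36:A>C MEH2:G>A L232:T>C M346:T>A L54:C>G
            R-M207 M207:A>G M306:C>A P224:G>T P227:C>G P229:A>T P232:G>C P280:T>A P285:C>A
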