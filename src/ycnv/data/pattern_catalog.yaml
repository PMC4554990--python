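# Catalog of named Y-chromosome CNV pattern signatures.
#
# Each signature lists the copy states required of annotated MSY regions
# (states: deleted | duplicated).  Regions not listed are wildcards except
# that a matched signature must also account for every fully non-normal
# region observed in a sample (see ycnv.patterns.classify).  The amplicons
# without probe coverage (g1, r1, r2, g4) are never required: their state
# is inferred only through their cataloged neighbours.
patterns:
  - name: "gr/gr del (c8)"
    requires: {gr1: deleted, gr2: deleted}
  - name: "gr/gr dupl (c9)"
    requires: {gr1: duplicated, gr2: duplicated}
  - name: "gr/gr dupl + distal dupl"
    requires: {gr1: duplicated, gr2: duplicated, r3: duplicated, r4: duplicated}
  - name: "distal gr dupl"
    requires: {gr2: duplicated}
  - name: "b2/b3 del (c35)"
    requires: {U3: deleted, b3: deleted}
  - name: "b1/b3 del (c3)"
    requires: {b3: deleted}
  - name: "b2/b4 del dupl (c9)"
    requires: {Y1: deleted, Y2: deleted, b3: duplicated, b4: duplicated}
  - name: "b2/b4 dupl (c21)"
    requires: {b3: duplicated, Y1: duplicated, g2: duplicated, r3: duplicated,
               r4: duplicated, Y2: duplicated, b4: duplicated}
  - name: "blue-grey dupl (c449)"
    requires: {gr1: duplicated, gr2: duplicated, U3: deleted}
  - name: "blue-grey like dupl"
    requires: {gr1: duplicated, gr2: duplicated, r3: duplicated, r4: duplicated,
               U3: deleted, Y1: deleted, Y2: deleted, g2: deleted}
  - name: "Y1Y2 dupl"
    requires: {Y1: duplicated, Y2: duplicated}
  - name: "IR2 dupl"
    requires: {IR2: duplicated}
  - name: "IR2 del"
    requires: {IR2: deleted}
  - name: "P6 dupl"
    requires: {P6: duplicated}
  - name: "P5 dupl"
    requires: {P5: duplicated}
  - name: "P4 dupl"
    requires: {P4: duplicated}
  - name: "P3 dupl"
    requires: {P3: duplicated}
  - name: "P3 del"
    requires: {P3: deleted}
  - name: "prior P5 post P4 dupl"
    requires: {preP5: duplicated, postP4: duplicated}
  - name: "q-arm dupl + U3 del"
    requires: {USP9Y-3p: duplicated, U3: deleted}
  - name: "q-arm del"
    requires: {AZFa-q: deleted, USP9Y-3p: deleted}
  - name: "q-arm del + U3 del"
    requires: {AZFa-q: deleted, USP9Y-3p: deleted, U3: deleted}
  - name: "p-arm dupl (PCDH11Y)"
    requires: {PCDH11Y-up: duplicated}
  - name: "p-arm dupl (AMELY)"
    requires: {AMELY-TBL1Y: duplicated}
  - name: "q-prox dupl (NLGN4Y)"
    requires: {NLGN4Y-up: duplicated}
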