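# Methods

`ycnv` reconstructs a complete Y-chromosome copy-number analysis from
per-probe log2-ratio intensities on the male-specific region (MSY):
probe/region annotation, QC, segmentation, named-pattern classification,
haplogroup assignment, enrichment statistics and PCA, together with a
synthetic-cohort generator that makes every stage testable without array
data.  This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Intensity model

The MSY is haploid, so probe copy states are 0 / 1 / 2+ rather than
diploid genotypes.  Per-probe log2 ratios are modeled as normal around
three state means taken from empirical Affymetrix-6.0-scale anchors:

| state | mean (log2 ratio) |
|---|---|
| one copy (male baseline) | −0.47 |
| zero copies (deletion / female background) | −2.02 |
| two copies (duplication) | 0.04 |

The per-probe noise s.d. defaults to σ = 0.25.  No published per-probe
variance exists for this setting; 0.25 was chosen once as a realistic
array noise level (it makes single-probe state calls unreliable — gain
calls sit ~1σ from threshold — which is exactly the regime the caller has
to handle) and is exposed in `IntensityModel.sigma`.

Female profiles additionally carry three fixed "hot" background intervals
(default mean −0.30) emulating cross-hybridising MSY windows; the hot
mean applies to any zero-copy probe inside those intervals, so it also
affects male deletions that overlap them.

## Synthetic manifest and region map

The default manifest is an evenly spaced grid over a 2.65–28.8 Mb
MSY-like span (2000 probes by default; 8179 for real-scale work, the
probe count of the array being emulated, of which ~288 are SNP probes).
Two deviations from uniformity mirror the emulated array: the AZFc
amplicons g1, r1, r2 and g4 carry no probes at all (their copy state is
reported as `no-probe` and only ever inferred through cataloged
neighbours), and the 35-kb window at the 3' end of *USP9Y* is filled to
21 probes at real scale, the locally doubled density the real array has
there.

Regions are STS-delimited, 1-based fully closed intervals (UCSC display
convention); a region runs from its left marker's start to its right
marker's stop, marker interiors included — the inclusive choice is a
determinism decision, since marker interiors have no canonical owner.
Adjacent regions that share a bounding marker (P5/P4, P3/U3, gr1/b3,
b3/Y1) overlap by that marker's width; probes may therefore belong to
several regions.  Coordinates in the bundled map are fixtures except for
four anchors with known hg19 positions (P6 18,279,605–18,843,147; the
*USP9Y* 3' window 14,939,249–14,974,460; the 782-kb proximal-q interval
14,448,577–15,230,545; the *PCDH11Y*-upstream window
4,654,108–4,802,101).  Users with a real annotation supply their own
manifest/STS/pairing TSVs through the same loaders.

## Cohort generator

`simulate_cohort` draws, per major haplogroup, a configured number of
males; each sample carries at most one named CNV pattern, drawn from its
haplogroup's per-pattern probabilities.  The default configuration
encodes the reference cohort shipped in `ycnv/data/table*.tsv`: 1506
haplogroup-assigned males, 221 carriers (14.7%), with the ten
overrepresented patterns at their tabulated per-haplogroup counts and the
remaining fifteen patterns allocated so each haplogroup's total carrier
count matches its any-CNV count (the allocation is
`defaults.EXTRA_PATTERN_COUNTS`; e.g. the widely distributed gr/gr
duplication gets 38 carriers, 2.52% of the cohort).

A pattern becomes concrete events by setting its required regions' probes
to the target state and emitting maximal constant-state runs (deletions
win the few probes where overlapping regions disagree).  Event ends are
jittered by up to `jitter_probes` (default 2) probes to emulate the
boundary heterogeneity of recurrent duplications, without crossing a
neighbouring event.  Genotypes are derived along the root path of the
bundled 18-node, 91-SNP haplogroup tree, ancestral elsewhere, with
independent missingness (default 5%).

What the generator does *not* emulate: GC waves and batch effects,
probe-specific affinities, multi-copy (>2) states, mosaicism, linked
marker noise, and real phylogenetic SNP density.  Green tests therefore
demonstrate the pipeline's correctness under its stated noise model, not
performance on real arrays.

## QC

Sex is inferred from the mean MSY log2 ratio against the midpoint of the
one- and zero-copy means (−1.245); exact ties — probability zero under
the model — go to male for determinism.  High-female-background probes
are blacklisted per disjoint 3-probe window when the across-female window
mean exceeds a threshold.  The default threshold is the male mean −0.47;
an alternative convention of −0.51 exists in the same source material and
is reachable via the `threshold` argument.  Blacklisted probes are
removed before segmentation.

## Segmentation

The original analysis used a closed-source caller plus manual curation;
`ycnv` replaces it with a transparent threshold-run-merge caller,
parameterized by the two settings that are documented (minimum 3 markers
per segment, minimum genomic size 5 kb):

1. the profile is smoothed with a centered moving average
   (`smooth_window`, default 5, odd; 1 disables);
2. per-probe states are called against thresholds at the midpoints of the
   state means (loss < −1.245, gain > −0.215; ties → normal);
3. maximal single-state runs are merged across interior discordant gaps
   of at most `max_gap` probes (default 1; endpoints always concordant);
4. runs failing `min_markers` or `min_size_kb` are dropped;
5. segments below `min_density` (default 0.05 probes/kb) are removed —
   this density filter is the automated surrogate for the manual
   curation of spurious calls in probe-poor sequence.

The smoothing step is load-bearing.  At σ = 0.25 the gain threshold lies
only ~1.02σ from both the one- and two-copy means, so unsmoothed
single-probe calls mis-state ~15% of probes on either side of a
duplication boundary; measured duplication recovery was then ~81%
(fragments at event edges fall below `min_markers`, and miscalled outside
probes chain into runs).  Averaging 5 probes moves the margin to ~2.3σ.
Crucially the window is centered and the thresholds are midpoints, so in
the σ→0 limit every state transition of ≥3 probes keeps its *exact*
boundary probes (the edge window mean crosses the midpoint exactly at the
first in-event probe) — the noise-free caller still equals the implanted
truth probe-for-probe, which the tests assert.  With defaults, balanced
deletion/duplication events of ≥20 probes are recovered with both
breakpoints within 2 probes in ~96–98% of simulations.

`max_gap` = 1 is also a measured optimum under this model: 0 lets
single-probe misses fragment runs whose pieces are then dropped, ≥2 lets
isolated miscalled outside probes chain across double gaps and overshoot
breakpoints.

## Pattern classification

Segments reduce to one state per region by probe coverage: a region is
`deleted`/`duplicated` when ≥ `coverage_threshold` (default 0.8) of its
probes lie inside loss/gain segment extents, `partial` when coverage is
positive but sub-threshold, `no-probe` when it has no probes.  The 0.8
default is the quantitative surrogate for by-eye plot reading: high
enough to reject the few-percent coverage that stray segments produce,
low enough to tolerate jittered boundaries and edge noise.

Classification is a greedy cover over the signature catalog: among
signatures whose requirements the vector satisfies, the one with most
required regions wins (ties lexicographic), its regions are struck, and
matching repeats — so a sample can legitimately carry two independent
patterns (e.g. a P6 duplication plus an AZFc deletion).  Only fully
`deleted`/`duplicated` regions demand explanation; `partial` states are
treated as noise-level evidence and never force a mismatch.  Any
remaining unexplained regions produce a single `novel` call with a
canonical signature string — unknown combinations are surfaced, never
dropped.  The bundled catalog holds 25 uniquely named signatures at the
region-state level; it is data (YAML), not code, because region-state
definitions of the named patterns are a transcription with judgment
calls, and users can edit or extend them.

## Haplogroup assignment

A genotype is placed at the deepest node with at least one observed
derived defining allele.  Missing calls are uninformative, never
contradictory.  Derived evidence on a branch disjoint from that node's
root path, or an observed-ancestral node *on* the path, makes the call
`ambiguous`; no derived allele anywhere makes it `unassigned`.  A node
whose tested children are all observed ancestral is reported in exclusion
notation (`NO-M214(xM175)`).  Within-node conflicts (one SNP derived,
another ancestral on the same node) count as positive support — a
declared simplification of the reference algorithm's unpublished
weighing.

Backmerging maps calls to a fixed 12-major set.  A call strictly below a
major maps to its nearest major ancestor.  A call at or above nodes with
major descendants resolves only if it is itself a major and every branch
towards deeper majors was *observed* ancestral; otherwise the sample is
flagged `excluded_internal` and leaves the tabulations, mirroring the
treatment of internal-node assignments (DE-M145, IJ-M429, P-P295).

## Enrichment statistics

Per variant, a haplogroup × carrier/non-carrier table over assigned
majors only (ambiguous/unassigned/excluded samples never enter; a sample
counts once however many matching events it has).  Statistics: Pearson
chi-square and likelihood-ratio G (via `scipy.stats.chi2_contingency`),
Fisher's exact test — exact two-sided for 2×2, fixed-margin Monte Carlo
(Patefield sampling, default 10⁶ replicates, seeded, standard error
reported) for r×c — and per-cell residuals in *both* conventions,
standardized (O−E)/√E and adjusted (O−E)/√(E(1−r/N)(1−c/N)), because the
reference tabulation demonstrably mixes the two between cells.  The
frequency report rounds percentages to 1 d.p. and can exclude whole
haplogroups from numerator and denominator alike.

## PCA

Alleles encode as G=1, C=2, T=3, A=4, missing=0 — a deliberately literal
reproduction of the reference encoding, statistically odd since missing
sits on the allele scale; mean imputation is available behind
`impute_missing` and off by default.  Zero-variance columns are dropped
(logged) — the only well-defined option before correlation scaling —
then components come from the SVD of the standardized matrix (equivalent
to the correlation-matrix eigendecomposition, which the tests verify
independently).  Component signs are fixed by making each component's
largest-magnitude loading positive.

## Numerical details

- Coordinates are 1-based closed everywhere; interval length is
  stop − start + 1.
- Threshold comparisons after smoothing carry a 1e-9 guard so exact ties
  stay "normal" despite cumulative-sum float error; sex inference guards
  its midpoint tie the same way.
- All randomness flows through `numpy.random.Generator`; every public
  simulation entry point is reproducible from (inputs, seed), and the
  pipeline derives stage seeds from one master seed.
- Recovery benchmarks score an implanted event by the envelope of
  same-state segments overlapping it — the quantity the region-coverage
  step actually consumes — requiring both envelope breakpoints within 2
  probes of truth.

## Problem sizes used in checks

Reference statistics are exact recomputations from the bundled count
tables (n = 1506).  Simulation checks use the real-scale manifest:
segmentation recovery over 500 single-event profiles; one carrier per
catalog signature for the round trip (realized at canonical boundaries —
jitter is cohort heterogeneity, not part of the per-signature exemplar);
calibration over 10 + 10 samples; 2000 null replicates for the type-I
check; and one full-scale (1506-male) cohort through the whole pipeline
at 2000-probe resolution.

## Known limitations

- The caller resolves only loss/normal/gain; copy numbers above 2 and
  mosaicism are out of scope, as is HMM/CBS-style segmentation.
- Catalog signatures are region-state transcriptions, not
  breakpoint-sequence definitions; two historically distinct variants
  with identical region-state footprints would be conflated.
- Printed omnibus p-values of the reference analysis are not
  reproducible from its printed counts under any standard construction
  tried here; the statistics are therefore validated against independent
  oracles (enumeration, loop sums, eigendecomposition), with the
  residuals and frequencies — which do regenerate — pinned in tests.
- The bundled tree is a fixture adequate for the 12 majors and the
  exclusion/backmerge logic, not a current reference phylogeny.
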