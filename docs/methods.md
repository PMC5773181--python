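# Methods

## Scope and data model

`chromoreg` analyses the positional organisation of differential gene
expression along chromosomes.  Its inputs are an annotation of flat,
stranded gene intervals (GFF3; protein-coding genes and tRNAs) and a
per-gene differential-expression call table from an upstream pipeline
(CuffDiff-style: expression values under the two conditions, log2 fold
change, q-value, significance flag).  Read mapping and DE testing are
deliberately upstream of this package; states are taken from the table's
own significance calls rather than re-derived, because re-thresholding
would silently change the upstream model's multiple-testing behaviour.
A fallback (`q ≤ α`, default α = 0.05) exists for tables without a flag.

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
and BED (0-based half-open) are converted at the I/O boundary.  Genes tie
on identical start by `(end, id)` for a deterministic ordering.
Overlapping adjacent genes still form a pair, with an empty intergenic
interval.

### Orientation of adjacent pairs

With genes ordered by coordinate, the pair orientation is a function of
the two strands: `FF` (+,+), `RR` (−,−), `RF` (−,+), `FR` (+,−).  `RF`
is defined as (left on reverse, right on forward) because only that
configuration puts **both** 5′ regulatory regions in the single
intergenic interval between the genes — the geometric precondition for a
shared regulatory element driving both.  This mapping is our inference;
the convention is not stated explicitly in the source material but no
other assignment is biologically coherent.

## Concordant-window scan and permutation null

A window of `k` consecutive genes (default 6) qualifies when
`(n_U ≥ m ∧ n_D = 0) ∨ (n_D ≥ m ∧ n_U = 0)` with `m = 4` by default.
Windows slide with step 1 and never span chromosomes for the observed
statistic.  The defaults balance two failure modes: shorter segments give
too little evidence of regional co-regulation, while requiring all `k`
genes to respond would miss regions under positional control in which
some genes simply lack a responsive transcription factor under the
contrast (most genes are constitutive under any single contrast).

The null hypothesis is that the *ordering* of states along chromosomes is
random given the genome's state composition.  Each iteration joins the
per-chromosome gene lists, applies a uniform seeded shuffle to the joined
state list (preserving the exact U/D/O multiset — a permutation, not a
binomial resample), and recomputes the qualifying fraction over the
joined list's sliding windows.  Windows spanning former chromosome
junctions are irrelevant after shuffling, so the joined-list fraction is
an unbiased null counterpart of the per-chromosome observed fraction.
The p-value is `exceedances / n_iterations`.

Numerical notes:

* Tie rule: the default counts null fractions `≥` the observed one
  (conservative standard; avoids p = 0 on degenerate inputs such as an
  all-constitutive genome, which correctly yields p = 1).  A
  `strictly_greater` rule is available; the difference is negligible for
  genuinely clustered genomes.
* No plus-one correction by default; `(b+1)/(N+1)` behind a flag.
* The shuffling is vectorised (row-wise permutation of a tiled state
  matrix); the chunk size is a fixed function of the genome length only,
  so results are bit-reproducible for a given `(inputs, seed)` regardless
  of batching.
* 100,000 iterations on a ~5,000-gene genome run in well under a minute
  on one CPU.

With the `≥` tie rule and an observed genome exchangeable with the null
draws, the p-value is uniform on a discrete grid **provided the statistic
has rich support**; with sparse differential expression the fraction has
large tie atoms (most random genomes contain 0 qualifying windows) and
the p-value is markedly conservative.  The test-suite calibration check
therefore uses state-dense replicate genomes (400 genes, p_U = p_D =
0.25) where the tie probability is small and a two-sided KS test against
uniformity is meaningful.  Passing it shows the permutation machinery is
calibrated, not that p-values on sparse real contrasts are exactly
uniform under the null (there they are conservative, which is the safe
direction).

### Cluster calls

Overlapping qualifying windows of the same direction merge; opposite
directions never merge.  The merged gene range is trimmed so the cluster
starts and ends at a gene of the cluster's direction — interior
constitutive genes remain absorbed (real clusters contain constitutive
members), but a flanking constitutive gene that merely rode along in a
4-of-6 window does not extend the cluster.  Each cluster reports the bp
distance from its span to the nearest tRNA gene on the same chromosome,
supporting the tRNA-as-insulator reading of cluster boundaries.

## Pair-association statistics

Informative adjacent pairs (at least one differentially expressed gene)
are cross-classified as concordant (`UU`, `DD`) vs discordant (`UO`,
`DO`, `UD`) — joint states are unordered — and common (RF) vs different
(FF, RR, FR) intergenic region; `OO` pairs carry no signal and are
excluded.  The likelihood ratio is

    L = [a/(a+c)] / [b/(b+d)] ,

the ratio of concordance probabilities given a shared vs non-shared
intergenic region.  Significance comes from Fisher's exact test; the
odds ratio is reported as the conditional maximum-likelihood estimate
under the noncentral hypergeometric model, with the sample odds ratio
`ad/(bc)` as a secondary field, and the two-sided p uses the
probability-ordering rule — both choices matching the standard R
implementation of the test, so the two estimates bracket what users of
that implementation expect.  Degenerate margins return p = 1 with the
odds ratio flagged NaN rather than raising.  The expected RF count under
random orientation is `n/4` of the informative pairs, since the four
orientations are equiprobable under independent equiprobable strands.

A cluster's concordant regulation is "explained" by outward transcription
to the extent its concordant genes sit in RF pairs whose partner is also
a concordant cluster member; the reported fraction is (genes in ≥ 1 such
pair) / (concordant genes in the cluster).

## Motif models and scanning

A pattern is an ordered list of allowed-base sets plus at most one
bounded spacer `N{lo–hi}` between two fixed blocks (the dimeric site
geometry).  The registry covers Mig1 (GC box; combined AT-box/GC-box),
Adr1 (half-site; dimeric model, which is its own reverse complement),
and Aft1/Aft2 (loose, strict PyPuCACCCPu, and exact variants).

Scanning reports every start position (overlapping hits allowed), both
strands by default.  Design choices:

* **Spacer policy**: one hit per left anchor using the shortest
  qualifying spacer (one biological dimer per anchor; avoids
  combinatorial inflation over a 2–36 bp gap); an all-spacers mode
  exists and is what the brute-force oracle in the tests compares
  against.
* **Palindrome deduplication**: a self-reverse-complementary pattern
  scanned on both strands would report every site twice; coordinate-
  identical duplicate hits collapse to one forward-strand hit.
* **Ambiguity**: sequence is case-folded; an `N` in the *sequence* never
  matches — including inside a spacer — so unknown bases cannot
  fabricate hits.
* Matching is implemented with compiled lookahead regexes (lazy
  quantifier for shortest-spacer selection); reported
  `matched_sequence` is the forward-strand text of the locus.

Context assignment: a hit inside a gene is `inside`; an intergenic hit
within the upstream window (default 1,000 bp — the conventional yeast
promoter span; truncated at the flanking gene by construction) of the 5′
start of exactly one flanking gene is `upstream-of` it; within both
flanking genes' upstream regions (an RF pair's shared interval) it is
`intergenic` with both genes listed; otherwise `downstream-of` the
nearest flanking gene.

## Synthetic genomes

The generator emulates the statistical skeleton of a compact multi-
chromosome yeast genome under a two-condition contrast:

* Layout: per-chromosome gene counts; truncated-normal gene lengths
  (default mean 900 ± 200 bp, min 200) and intergenic gaps (250 ± 80,
  min 60) — compact yeast-like spacing; a 2 kb telomeric gap at each end.
* Strands: i.i.d. with configurable forward probability, or fixed.
* States: exact genome-wide counts (hypergeometric-style placement; the
  default when integers are given, because recovery tests need exact
  composition), i.i.d. frequencies, or fully explicit per-gene states.
* Planted clusters place their concordant genes contiguously from the
  left (centromere-proximal) edge with the remainder constitutive, and
  can retype the immediately downstream gene as a tRNA flank.
* Subtelomeric zones force the outermost genes of every chromosome to
  low, equal expression under both conditions with a non-significant
  call — silent regions that are non-responsive to the contrast.
* Sequence: i.i.d. uniform A/C/G/T (making analytic false-positive rates
  exact), with motif instances sampled from their pattern and written
  verbatim at recorded coordinates.
* The DE table is generated consistently with the planted state (flag,
  fold-change sign, q-value range, value₂ = value₁·2^log2FC).

The study-scale configuration used in tests has 8 chromosomes, 5,162
genes, exactly 323 `U` and 245 `D`, three planted 6-gene up-regulated
clusters (two with tRNA flanks) and 8-gene subtelomeric zones.

What the generator does **not** emulate: expression-level noise
structure, operon-like correlated strand runs, GC heterogeneity, repeat
families, or realistic q-value distributions.  Tests passing on these
genomes demonstrate correctness of the machinery (exact recovery of
planted signals, calibration under known nulls), not biological
performance on real RNA-seq contrasts.

### Planting a contingency table

`plant_contingency` builds a genome whose pair classification equals a
requested 2×2 table plus an `OO`-pair count, preferring a single
chromosome: alternating `U`/`D` runs supply the concordant pairs and the
run junctions the discordant ones, a trailing constitutive run supplies
the excluded pairs, and RF orientations are placed greedily on
non-adjacent pairs (two RF pairs can never be adjacent, since the right
gene of one RF pair is on the forward strand).  Configurations where the
single-chain adjacency constraint is infeasible (e.g. every pair must be
RF) fall back to a compact multi-chromosome layout of 2-gene islands.
The construction is verified by re-classifying the generated genome; an
infeasible request raises a configuration error.

## Problem sizes in the test suite

The suite checks the permutation engine against exhaustive enumeration
on 12-gene genomes (all 924 distinct orderings), runs the study-scale
planted-cluster scan at the full 100,000 iterations, and uses 200
replicate genomes × 5,000 iterations for the uniformity calibration;
motif-scanner oracle equivalence uses 100 random 2-kb sequences per
pattern.  These sizes keep the full suite under a couple of minutes on
one CPU while leaving every statistical check adequately powered.

## Known limitations

* Genes are flat intervals: no transcript/exon structure, so "upstream"
  is measured from the annotated gene start, not a mapped TSS.
* The window scan has no multiple-testing control across alternative
  window lengths; `k` and `m` are fixed choices, as in the underlying
  analysis design.
* Motif hits are pattern matches, not affinity predictions; no PWM
  scoring or enrichment p-values are computed.
* The association test is global; no per-chromosome stratification or
  covariate modelling of concordance.
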