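# Methods

`svpop` re-implements, as a tested library, a population-scale long-read
structural-variant (SV) workflow: per-sample multi-caller consensus,
quality filtering, allele-balance genotyping, population-level
nonredundant merging with frequency classification, coding-impact and
repeat annotation, external-dataset comparison and truth-set FDR, and an
F_ST/PBS differentiation scan.  Because the cohort data such workflows
run on are access-restricted, the package ships a first-class synthetic
generator that reproduces the statistical structure of such a study and
provides ground truth for every stage.

## Coordinates and the insertion convention

All internal coordinates are 0-based, half-open; VCF/GTF I/O converts at
the boundary.  An insertion's reference footprint is a point, which makes
interval-overlap criteria degenerate; every INS therefore carries the
synthetic interval `[start, start + svlen)` so that both position and
inserted length enter the overlap computation.  Population VCF output
writes the conventional `END = start + 1` and keeps the synthetic end in
`INFO/SYNEND`.

## Ensemble merging (CAST)

Within a sample, the three callers' calls are pooled per chromosome and
SV type and segregated into non-overlapping groups — connected components
of the interval-intersection graph, computed by a sorted sweep and
verified in the tests against a quadratic union-find oracle.  Each group
is clustered with the Cluster Affinity Search Technique (CAST) over the
pairwise affinity `reciprocal_overlap(a, b) = min(shared/len(a),
shared/len(b))` with threshold 0.5 ("at least 50% mutual overlap", so >=).
CAST details are underdetermined in the literature it comes from, so the
implementation fixes them for reproducibility:

* seed = unassigned node with the most above-threshold neighbours;
* ADD (highest average affinity to the open cluster, if >= 0.5) is
  evaluated before REMOVE (lowest average affinity among members, if
  < 0.5);
* ties broken by (smaller start, longer svlen, caller priority);
* an iteration bound of `4 n^2 + 16` guards against add/remove cycles.

Clusters supported by >= 2 distinct callers survive; the representative
is the Sniffles member if present, else NanoVar, else NanoSV (the
priority reflects the callers' relative precision on ONT reads), with
higher support and smaller start breaking ties within a caller.  On 500
random groups of <= 6 intervals, the CAST partition attains the
exhaustive-search optimum of the threshold-centred score
`sum_within(affinity - 0.5)` in 99% of trials.

## Filtering

Three commuting filters, with per-step removal accounting: (1) support —
representative backed by >= 3 reads, or `round(0.2 x mean depth)` in
depth-scaled mode (equal to 3 reads at 15-fold); (2) length — DEL/INS
capped at 2 Mb, DUP/INV at 5 Mb, everything below 50 bp dropped; (3)
region — any 1 bp intersection (the BEDTools default) with centromere,
assembly-gap or >= 500x high-depth masks removes the call.

## Genotyping and the population set

The variant allele balance VAB = supporting reads / site depth maps to
genotypes as 0/0 for VAB <= 0.2, 0/1 for 0.2 < VAB <= 0.8, 1/1 for
VAB > 0.8; unknown or zero depth gives `./.`.  The test suite checks the
bands exhaustively (all depth <= 100 pairs) with rational arithmetic.
One subtlety: with integer read counts the 0.2 boundary is attainable
exactly when depth is a multiple of 5, so heterozygote miscalls into 0/0
slightly exceed those into 1/1 (net ~ -0.004 per het at 15-fold); the
resulting AF underestimate stays below 0.002 and is asserted as such.

Cross-sample merging reuses the CAST machinery; the representative of a
population cluster is the member whose (start, svlen) pair occurs in the
most samples (ties: higher support, then smaller start).  Samples without
a member are genotyped 0/0 — the whole cohort enters every AF
denominator; `./.` is reserved for depth-unknown members.  Sites are
classed singleton (AC = 1), rare (AC > 1, AF <= 0.01), low
(0.01 < AF <= 0.05) or common (AF > 0.05).  A site whose carriers all
genotype 0/0 (AC = 0) is kept but unclassified.  Sex chromosomes are
treated as diploid.

The discovery curve re-merges random subsets of increasing size and
averages per-category counts over replicates.  With a finite simulated
locus pool the singleton curve rises only while the subset is well below
the full cohort (the discovery regime, mirroring a 100-of-405 to full
sweep); approaching the full cohort it saturates, because no loci beyond
the generated pool exist to discover — a desk-scale artifact, not a
property of real cohorts.

## Annotation

Coding impact: a DEL overlapping >= 1 CDS, an INS inserted strictly
inside a CDS (boundary positions excluded), or a DUP/INV partially
overlapping a CDS is predicted loss-of-function (pLoF); a DUP/INV
containing an entire gene span is a whole-gene duplication/inversion
(WDUP/WINV) for that gene instead, and one SV can be both WDUP/WINV for
one gene and pLoF for another.  Gene features follow the precedence
CDS > UTR > promoter > intron > intergenic: CDS by interval overlap,
UTR/promoter by breakpoint (interval endpoint) containment, intron when
both breakpoints fall in one gene's span.  Promoters are the 1 kb
strand-aware window preceding the TSS, clipped at the chromosome start.
Repeat classification takes precomputed repeat intervals: the family
covering (after per-family union) more than half of the SV's length wins;
a winning tandem annotation with repeat unit >= 7 bp is a VNTR.
Enrichment per (category, feature) cell uses a two-sided Fisher exact
test on the 2x2 table against the rest of the population set, with
Benjamini-Hochberg correction across cells; tests verify the p-values
against a direct hypergeometric enumeration.

## Comparison and FDR

Dataset matching requires the same type and reciprocal overlap strictly
greater than 0.5 (the merge step uses >=; both thresholds are
configurable and deliberately distinct).  External tables map CNV gains
to DUP, losses to DEL and mobile-element insertions to INS, and drop
insertions without a usable length.  Novelty is measured against the
union of reference sets.  FDR = unmatched calls / calls, overall and per
type, reported to one decimal percent.

## Population genetics

Per-site differentiation uses Hudson's F_ST estimator with sample-size
correction; negative estimates clamp to 0 in the scan.  For calibration
across many sites the package uses the ratio-of-averages combination
(`hudson_fst_genome`) with a leave-one-site-out jackknife SE — averaging
per-site ratios is Jensen-biased (~ -10% at F = 0.05, n = 100 per group)
and is not used for that purpose.  The population branch statistic for
focal A is `[-ln(1-F_AB) - ln(1-F_AC) + ln(1-F_BC)]/2`, clamped at 0.
The scan keeps sites with pooled MAF > 0.01, thresholds at the empirical
99.9% rank of the focal scores, and chains above-threshold sites within
1 Mb on a chromosome into independent signals.  IBS similarity is
`mean((2 - |g_i - g_j|)/2)`; the Bonferroni helper reports
`alpha / n_tests` to two significant figures.

## The synthetic generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs:

* **Genome** — equal-length toy chromosomes (default 3 x 10 Mb) with a
  centred centromere (10%), two gap and one high-depth mask intervals
  each, and non-overlapping two-exon genes placed clear of masks and of
  each other's promoters.
* **Type mix** — DEL 0.444, INS 0.538, DUP 0.014, INV 0.004.
* **Lengths** — DEL/INS from a four-component mixture: lognormal body
  (median ~120 bp) 0.55, Alu-like N(300, 30) 0.35, LINE-like
  N(6000, 600) 0.07, long lognormal tail 0.03 — weights chosen to
  reproduce the two characteristic indel peaks; DUP ~ lognormal median
  1 kb, INV ~ lognormal median 5.5 kb.  Lengths cap at 100 kb because the
  extreme tail cannot be placed on Mb-scale toy chromosomes; loci are
  placed longest-first, non-overlapping (200 bp margin), outside masks,
  and outside gene bodies unless deliberately planted over a CDS as pLoF
  ground truth.
* **Frequencies** — ancestral AF ~ Beta(0.3, 2.0), floored at 1/(4N) and
  truncated to segregating sites by conditioning: non-segregating loci
  redraw their subpopulation frequencies and genotypes while the
  ancestral frequency stays fixed.  (Redrawing the ancestral frequency
  instead tilts the observed spectrum by the segregation probability and
  destroys the singleton-heavy tail.)  Subpopulation frequencies follow
  the Balding-Nichols model `p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`;
  genotypes are Binomial(2, p_k), i.e. Hardy-Weinberg within
  subpopulations.
* **Planted differentiated loci** — a Balding-Nichols draw at the target
  F realizes a chi-square-spread divergence and cannot reliably dominate
  a 99.9% rank threshold, so planted loci receive a deterministic focal
  frequency shift solving Hudson F_ST(p, p + d) = F_target, directed
  toward the farther AF boundary so clipping cannot erode it.  Even so,
  with 10 planted loci among 10,000 neutral ones the threshold is the
  ~10th largest score and recovery is intrinsically stochastic: across
  seeds 7-9 of 10 planted loci exceed the threshold.
* **Callers** — per-type sensitivity, breakpoint jitter (rounded normal),
  multiplicative length jitter, support ~ Binomial(site depth, 0.5 | 1.0)
  for het | hom with site depth ~ Poisson(mean 15), and Poisson false
  calls placed at least twice the longest truth SV from every truth
  locus.  Default profiles: sensitivities 0.95/0.90/0.85, jitter SD
  10/20/30 bp, length CV 0.03/0.05/0.08, false calls 300/500/800 per
  genome.  Output is deterministic given the seed (per-sample,
  per-caller child streams).

What the generator does not emulate: sequence context (calls carry no
alleles), alignment artifacts, depth heterogeneity along the genome,
caller-specific breakpoint biases, overlapping/nested true SVs, and
linkage disequilibrium between loci (sites are independent).  Passing
tests therefore validate the pipeline's combinatorial and statistical
behaviour, not robustness to read-level noise.

## Problem sizes

The validation suite exercises the pipeline at desk scale, chosen as the
smallest sizes at which the measured quantities have comfortable margins:
the noisy operating point runs 50 samples x 5,000 SVs at 15-fold depth
(measured FDR ~0.4%, common-SV recall ~99.9%); the selection scan 10,010
loci x 300 samples; calibrations 10,000 sites; the discovery curve a
90-sample cohort.  The clustering oracle enumerates all partitions of
groups of <= 6 calls (Bell(6) = 203).
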