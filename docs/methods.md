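# Methods

This note documents the models and procedures implemented in
`stagenet`, the parameter choices that matter, what the synthetic
cohort generator does and does not emulate, and the numerical
conventions that make runs reproducible.

## Pipeline overview

The package analyses a staged case/control bulk expression cohort in
two branches. The *gene-level* branch quantifies how expression
changes with stage: per-stage differential expression against control,
cross-stage signature comparison, and progressive-gene detection. The
*network* branch quantifies how co-expression changes: one
mutual-information network per phenotype, chromosomal (cis/trans)
topology, degree-distribution fits, multi-network intersections across
cut-offs, and community-level over-representation on the intersection
sub-networks.

## Normalisation

Counts are filtered by across-sample mean (strictly greater than 10,
applied to raw counts before any scaling) and normalised by TMM
(trimmed mean of M-values). For each sample against a reference (the
sample whose upper quartile of scaled counts is closest to the cohort
mean upper quartile), per-gene log2 ratios M are doubly trimmed — 30%
on M, 5% on average abundance A, rank-based — and averaged with
inverse-delta-method-variance weights; genes with a zero count in
either sample are excluded; factors are rescaled to geometric mean 1.
The implementation matches the Bioconductor edgeR `calcNormFactors`
reference to four decimals on shared inputs (cross-checked in the test
suite via Rscript). Downstream analyses use
log2-CPM, `log2((count + 1) / (libsize × factor) × 1e6)`.

Dataset-specific corrections (GC/length bias, batch removal) are out
of scope: the pipeline accepts pre-corrected matrices transparently,
and the synthetic cohorts have no batch structure.

## Differential expression and progressive genes

Log2 fold change is the difference of group means on the log2-CPM
scale; p-values come from a two-sided Welch t-test per gene, corrected
by Benjamini–Hochberg across genes; a gene is `over`/`under` when
|LFC| exceeds the threshold (2.0 vs control; 0.5 for the relaxed
all-pairs multi-group contrasts) at FDR < alpha (0.05). The Welch test
replaces count-model moderated estimators (empirical-Bayes moderation,
likelihood-ratio tests on GLMs): those estimators' internals are not
the subject of this package, and the test statistic is a pluggable
seam. Degenerate genes (zero within-group variance) get p = 1 when
the group means agree and p = 0 otherwise.

Progressive genes must (a) have strictly monotone group means across
the full phenotype order and (b) differ significantly in every
consecutive pair of stages by a two-sided Mann–Whitney rank-sum test,
with BH applied jointly across all gene × consecutive-pair tests
before thresholding. The rank-sum form is a deliberate choice: stage
groups are unpaired patient sets, so a signed-rank (paired) test has
no valid pairing; monotonicity is evaluated on means, matching the
multiplicative generative model of the planted genes.

Signature similarity between two contrasts is Spearman's rank
correlation (average ranks on ties) of the LFC vectors over the shared
gene universe.

## Mutual-information networks

Each pair of gene profiles is discretised by equal-frequency binning
with deterministic tie-breaking (stable sort; ties keep sample order),
and scored with the plug-in estimate of mutual information in bits
over the B×B contingency table; a Miller–Madow bias-corrected variant
is available. Equal-frequency binning makes the score exactly
invariant under strictly increasing transforms of either profile.
Edges are ranked by MI descending with lexicographic tie-breaking on
the canonical (sorted) gene pair, so top-N cut-offs are nested
prefixes of one deterministic ranking and runs need no seed.

**Bin count.** The library default is B = floor(√n). This rule is
sensible for cohorts of hundreds of samples but matters a great deal
at desk scale: the plug-in estimate carries an upward bias of roughly
(B−1)²/(2n ln2) bits, and at n = 60, B = 7 the independence null has
median ≈ 0.54 bits with p99 ≈ 0.79 — enough to swamp genuine
co-expression when tens of thousands of null pairs compete for a
top-1000 cut. At the other extreme, very coarse binning (B = 3)
saturates the MI scale at log₂3 bits and collapses the rank separation
among strong modules. The study and demo analyses therefore fix B = 5,
which keeps the null p99 (≈ 0.44 bits at n = 60) far below planted
signal (median ≈ 0.9 bits) while still resolving the top of the
ranking. The bin count and estimator are surfaced in
`MIEstimatorConfig`.

DPI pruning (remove, in each gene triangle, the weakest edge when it
falls below (1 − tolerance) × the smaller of the other two; all
removals applied simultaneously after a full scan) is provided but OFF
by default: the pipeline thresholds by rank, not by triangle
inequality, and the sweep over cut-offs is the primary sparsification.
No MI significance threshold is applied, for the same reason.

## Chromosomal topology

Edges are cis when both endpoints share a chromosome label after
stripping an optional `chr` prefix and case-folding (so GENCODE and
UCSC dialects mix). Two summary conventions coexist deliberately:

* **per-chromosome cis-rate** = cis edges on the chromosome / number
  of that chromosome's genes present in the network — a ratio that can
  exceed 1 on cis-dense chromosomes;
* **global cis fraction** = n_cis / (n_cis + n_trans).

Degree distributions p(k) are computed over network nodes (degree ≥ 1
by construction); the power-law fit y = a·k^b is nonlinear least
squares on the linear scale, initialised from the log–log OLS solution
(so noiseless power-law data is recovered to machine precision), with
Pearson correlation of fitted vs observed values and R² reported. The
fit accepts either normalised probabilities or raw counts on the y
axis. Largest components break size ties toward the component
containing the lexicographically smallest node.

## Intersections

Networks are compared as sets of canonical unordered gene pairs at
matched top-N sizes (equal sizes make proportions comparable; MI
values are ignored for membership). The full Venn decomposition is
computed by membership tally; the headline regions are the
all-phenotype shared set, the tumor-only set (present in every
non-control network, absent from control) and per-network specific
edges. `pairwise_divergence(a, b) = 1 − |a∩b|/|a|` for equal-size
sets. The cut-off curve reports |shared|/N and |tumor-only|/N at each
N of an increasing grid.

## Communities and enrichment

Community detection uses Infomap (python-igraph, two-level, 10
trials) with the RNG seeded per call, so partitions are deterministic
given (method, seed); a seeded label-propagation fallback is provided.
Community ids are renumbered by each community's smallest member, so
labels do not depend on detection order. Each community with at least
`min_community` (default 5) genes inside the universe is tested
against each gene set by the upper-tail hypergeometric probability
P(X ≥ k) with universe N = all genes surviving the mean filter (the
measured background, not the whole annotation), followed by BH across
all community × set tests. BH stands in for proprietary multiple-test
corrections used by hosted enrichment services; both target FDR 0.05.

## Synthetic cohort generator

The generator emulates a staged tumor/control bulk RNA-seq cohort with
three kinds of planted, recorded ground truth:

* **modules** — gene groups sharing a latent factor on the log-mean
  scale in the phenotypes where the module is active. A module's
  `latent_strength` is the fraction of its log-scale mean variance
  (total sd `module_log_sd`, default 1.5 natural-log units) carried by
  the shared factor. `cis_constrained` modules are forced onto a
  single chromosome (successive cis modules take successive
  chromosomes, keeping per-chromosome gene counts balanced); free
  modules keep round-robin chromosome assignments, making their pairs
  mostly trans.
* **progressive genes** — exact multiplicative mean steps
  (`fold_step`, default 2) per consecutive phenotype, up or down, so
  the monotone ground truth is unambiguous.
* **background** — independent negative-binomial noise.

Counts are NB(mean, dispersion) via the gamma–Poisson mixture
(variance = μ + φμ², φ = 0.1 by default — a typical bulk RNA-seq
dispersion), with a uniform per-sample depth factor in [0.8, 1.2] so
between-sample normalisation has real work to do. Identical configs
produce bit-identical cohorts.

Two abundance regimes are deliberate: module genes draw baseline means
log-uniformly from a moderate range (20–500) while background genes
span a heavy range (50–20,000). This keeps the planted modules a small
fraction of library mass, which is the regime TMM's
majority-unchanged assumption requires; in early designs where module
genes dominated the library, their latent swings moved every gene's
CPM and manufactured genuine common-mode dependence among "null"
pairs — a compositional artifact worth remembering when simulating
small panels.

**Standard study architecture** (`make_study_config`): five ordered
phenotypes; two disjoint arms of 10 modules × 15 genes. The control
arm is trans-rich (2/10 cis-constrained, planted cis pair fraction
≈ 0.24), the tumor arm — active in all four stages — cis-rich (8/10,
≈ 0.81), emulating the loss of long-range co-expression in tumors.
Each arm plants C(15,2) × 10 = 1,050 pairs, just above the top-1,000
network readout: the read-out networks fill from planted structure,
while no single module's latent draw can dominate the ranking. Module
`latent_strength` is 0.9 (tightly co-regulated programs, so recovery
readouts reflect topology statistics rather than estimator
sensitivity). The optional constitutive modules (active in every
phenotype) are compact — 2 × 9 genes, 72 pairs, fully latent-driven —
because the all-phenotype shared program must fit inside the smallest
cut-off for the shared proportion to decay monotonically with network
size; with a larger shared program the smallest cut-off necessarily
samples differing subsets per network and the first curve point
collapses, an arithmetic constraint rather than a biological one.
The demo profile scales this to 10-gene modules, 40 samples per
phenotype and cut-offs {100, 300, 1000}; the grid starts at 100
because below the 72 constitutive pairs phenotype-specific chromosomal
structure is undefined by construction.

**What the generator does not emulate**: GC/length bias, batch
effects, isoforms, library-size confounding beyond the scalar depth
factor, correlated module activity, overlapping modules, or any real
chromosomal gene order. Passing recovery tests therefore demonstrates
that the estimators and set machinery recover the structure they
target under honest count noise — not that the pipeline's biological
conclusions transfer to any particular real cohort.

## Problem sizes and numerics

The shipped analyses use 5 phenotypes × 40–60 samples and 264–366
genes (≈ 35,000–67,000 gene pairs per network), sizes chosen so the
full test suite and the acceptance script each run in about a minute
on one CPU while keeping ≥ 1,000 planted pairs per phenotype. All
randomness flows through explicit integer seeds
(`numpy.random.default_rng`); MI ranking, binning ties, community
renumbering and component tie-breaks are deterministic by
construction, so pipeline outputs are byte-identical across reruns.
Degenerate inputs have defined behaviour: constant profiles carry zero
MI (with a warning), zero-variance DE genes get p ∈ {0, 1} by mean
agreement, empty filter results warn rather than fail, and
non-convergent power-law fits raise an error carrying the log–log
fallback estimates.

## Known limitations

* The Welch t replaces count-based moderated tests; at very small
  group sizes its p-values on log-CPM are approximate.
* The plug-in MI bias grows as (B−1)²/(2n ln2); rankings are more
  robust than absolute MI values, and absolute MI comparisons across
  different n or B are not meaningful.
* The power-law fit is a descriptive curve fit on p(k), not a
  maximum-likelihood tail estimate; it does not adjudicate between
  heavy-tailed alternatives.
* Per-chromosome cis-rates depend on the annotation's chromosome
  granularity; scaffolds or patch contigs should be collapsed or
  filtered by the caller.
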