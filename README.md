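# stagenet

Stage-wise gene co-expression network analysis for bulk transcriptomes.

`stagenet` is for computational biologists who want to ask how a tumor's
*co-expression* program — not just its expression program — changes
across disease progression stages. Given a gene × sample count matrix,
a sample → stage labelling (control plus ordered tumor stages) and a
gene → chromosome annotation, it:

1. filters (mean > 10) and normalises counts (TMM scale factors,
   log2-CPM);
2. computes per-stage differential-expression signatures versus control
   (Welch t on log2 values, |log2FC| > 2, Benjamini–Hochberg FDR
   < 0.05), compares signatures between stages by Spearman rank
   correlation of the log-fold-change vectors, and detects
   **progressive genes** — genes whose group means change strictly
   monotonically across the ordered stages with every consecutive-stage
   difference significant (rank-sum tests, BH-adjusted jointly);
3. infers one co-expression network per phenotype by pairwise **mutual
   information**, I(X;Y) = Σ p(x,y) log₂ p(x,y)/(p(x)p(y)), estimated
   on equal-frequency-binned profiles with deterministic tie-breaking,
   ranked and thresholded to top-*N* edge lists (optionally pruned with
   the ARACNe-style data-processing-inequality rule);
4. splits every edge into **cis-** (both genes on one chromosome) or
   **trans-** (inter-chromosome) and summarises counts, per-chromosome
   cis-rates (cis edges / chromosome's genes in the network) and
   power-law fits p(k) = a·k^b to the degree distribution;
5. intersects the phenotype networks at matched top-*N* sizes — the
   sub-network shared by *all* phenotypes, the tumor-only sub-network,
   per-network specific edges — and tracks the shared proportions
   across cut-offs spanning orders of magnitude;
6. detects communities (Infomap) on the shared and tumor-only
   sub-networks and scores each community against gene-set collections
   with the upper-tail hypergeometric test, BH-corrected.

A first-class synthetic cohort generator plants known structure —
chromosome-constrained co-expression modules with phenotype-specific
activity, monotone progressive genes, negative-binomial count noise —
so every stage of the pipeline can be validated against ground truth.

## Worked example

The built-in demo study simulates a 264-gene, 5-phenotype cohort
(control + four tumor stages, 40 samples each) in which control-only
modules are trans-rich, tumor-shared modules are cis-rich, two compact
constitutive modules span all phenotypes, and four genes progress
monotonically (two up, two down, 2× per stage):

```bash
stagenet run --out demo_run --seed 1
```

or in Python:

```python
from stagenet.pipeline import demo_config, run_pipeline
run_dir = run_pipeline(demo_config("demo_run", seed=1))
```

Key numbers from `demo_run/manifest.json` at seed 1:

```
trans interactions per cut-off (control vs stages):
  cutoff  control  stage_i  stage_ii  stage_iii  stage_iv
  100     52       32       34        29         44
  300     212      81       76        70         109
  1000    824      573      595       562        574

progressive genes: G0218 up, G0219 up, G0220 down, G0221 down
shared by all 5 networks (top-1000): 76 edges
tumor-only (in every stage, absent from control): 362 edges
```

Reading these the way the method intends: the control network keeps
more long-range (trans-) co-expression than every tumor network at
every cut-off — the planted loss-of-trans signature — while the
recovered progressive genes are exactly the four planted ones with
their directions. The 76 all-phenotype edges recover the two planted
constitutive modules (72 true pairs), and the 362 tumor-only edges come
from the tumor-arm modules; community enrichment on both sub-networks
flags the planted modules at FDR < 0.05.

Per-stage artifacts (normalised matrix, DE tables, ranked edge lists,
topology summaries, GraphML giant components, intersection curve,
enrichment tables) land under the run directory and are indexed in
`manifest.json`. Re-running with the same seed reproduces every file
byte-for-byte.

## Command-line interface

Each pipeline stage is also exposed as a subcommand over the standard
TSV/GMT/GraphML formats:

```
stagenet simulate|preprocess|de|progressive|infer|topology|compare|enrich|run
```

e.g. `stagenet infer --normalized N.tsv --labels L.tsv --control
control --phenotype stage_i --bins 5 --top 10000 --out edges.tsv`.

See `docs/methods.md` for the model, estimator choices, generator
design and known limitations.
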