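# Methods

## Scope and model

The package implements a network-inference chain over miRNA target sets and
pathway gene graphs:

1. effective-target curation (predictor-support filter ∩ fold-change DEGs),
2. distance-k subpathway mining,
3. a hypergeometric-thresholded bipartite miRNA–subpathway network,
4. one-mode projections by a cumulative hypergeometric co-regulation test,
5. power-law topology summaries and clique-percolation modules,
6. a two-miRNA k-means split of a patient cohort compared by
   Kaplan–Meier / log-rank.

Every stage is a library function under `src/mirsubnet/`; the numbered
scripts under `analysis/` are thin drivers over those functions, and the
synthetic generator (`mirsubnet.simulate`) supplies inputs with known
planted structure so each claim the pipeline makes can be scored against
truth labels.

## Statistical details

**Enrichment and co-regulation tests.** Both use the upper-tail
hypergeometric probability *including* the observed count, P(X ≥ j), the
standard over-representation convention; j = 0 therefore gives P = 1
exactly, and the test is symmetric in the two set sizes. Enrichment draws
are `targets ∩ universe`, where the default universe is the union of genes
over all supplied pathways — the natural population for pathway-level
enrichment; a custom universe can be passed instead. No multiple-testing
correction is applied by default: edges are defined by thresholding raw
p-values (0.05 bipartite, 0.01 miRNA pairs, 0.001 subpathway pairs), with
the miRNA threshold strict (<) and the subpathway threshold non-strict (≤).
All thresholds and strictness are configurable.

**Projection population n.** For miRNA–miRNA pairs the pipeline takes n =
the number of *all mined* subpathways (the population the bipartite network
was built from); for subpathway–subpathway pairs n = the number of miRNAs
observed to regulate at least one subpathway. The distinction matters: in a
small or saturated network, using only the observed subpathway nodes makes
every heavily-shared neighbor set its own population (m = i = j = n forces
P = 1) and destroys the test's resolution. The standalone `project()`
function defaults to the observed-nodes convention and accepts
`all_mined` / `user_value` with an explicit total, so either reading can be
applied to external data.

**Subpathway mining.** A pathway is an undirected gene graph; subpathways
at distance parameter k (default 4) are exactly the maximal cliques of the
"closeness graph" joining gene pairs at shortest-path distance 1..k.
Maximal cliques come from Bron–Kerbosch with pivoting (networkx
`find_cliques`); output is ordered deterministically by lexicographically
sorted gene lists and numbered `<pathway>_<j>`. No minimum-size filter is
applied by default (`min_genes=1`). Identical gene sets mined from
different pathways remain distinct subpathways.

**DEG calling.** Fold change is the ratio of arithmetic group means on the
linear scale (not a mean of per-sample ratios); a gene is differentially
expressed when the ratio is ≥ 1.5 or ≤ 1/1.5, both directions, with no
sign-matching against the miRNA's own direction. Genes with a non-positive
group mean are excluded with a warning — values are assumed
background-corrected and positive. When several expression series are
available, per-series DEG sets are merged by union (default) or
intersection (`combine_degs`).

**Power-law fit.** Ordinary least squares on (log k, log count) of the
degree-distribution points with k ≥ 1; the exponent a is the slope, β the
exponential of the intercept, R² the coefficient of determination on the
log–log data, and the separate correlation column the Pearson correlation
between observed counts and the fitted curve on the original scale. This is
deliberately the simple line-fit convention of network-visualization tools,
not maximum-likelihood power-law estimation; natural logs are used
internally (a and R² are base-invariant).

**Clique percolation.** k-cliques are enumerated as size-k subsets of the
maximal cliques (exact, and fast at tens of nodes); two k-cliques are
adjacent when they share exactly k−1 nodes, and communities are the
connected components of that clique graph. Communities exist only for
k ≥ 2; isolated nodes never appear; a fixed-k call is the primary
interface, with `cpm_sweep` covering all feasible k.

**Survival.** The two miRNA expression values are standardized to zero
mean / unit variance before 2-means (the two measurements need not share a
scale; disable with `standardize=False`). KMeans uses 25 restarts from a
seeded state and the labeling convention "group 1 = higher mean expr_a",
which reproduces a "high miRNA-A / low miRNA-B" grouping when the two
miRNAs shift oppositely. Kaplan–Meier and the log-rank test are delegated
to lifelines; the log-rank statistic is the standard observed-minus-expected
chi-square with hypergeometric variance, ties handled by evaluating all
deaths at a tied time against one risk set (the test suite keeps an
independent hand-tabulation oracle for both).

## Synthetic data: what it emulates and what it does not

`SimulationConfig` defaults are the study conditions: 56 miRNAs (24 up, 32
down), an 89-patient cohort, k = 4 mining, the ≥4-of-11 support filter and
the 1.5-fold DEG threshold. Quantities the study does not pin down were
chosen once as realistic for this kind of data and are not tuned: 20
pathways of 40 genes, a 1200-gene universe, a target budget of 60 genes per
miRNA with a 2% background target rate, log2 fold changes of 0.85–2.0 with
σ = 0.2 Gaussian noise on 10+10 samples, exponential survival with a
36-month baseline median, hazard ratio 3 between latent groups, 30%
independent censoring, and a ±1.5 SD two-miRNA mean separation.

Pathway graphs are simple generators (path, ring lattice, rewired
small-world) rather than curated-pathway mimics: subpathway mining depends
only on graph distances, so topology choice affects subpathway shape, not
the correctness being tested. Path topology (the default) yields
sliding-window subpathways at k = 4, which keeps the mined population large
and regular.

Planted structure: each planted group's members draw a configured fraction
of their target budget from the genes of shared subpathways (chosen
deterministically from the mined list, or given explicitly), the remainder
uniformly at the background rate. Planted targets always pass the support
filter and are always DEGs; background targets pass the support filter at a
configured rate (default 0.5) and are DEGs at 0.7. Truth labels (group
membership, shared subpathway ids, per-gene target origin, DEG set, latent
survival group) are recorded in the bundle, so recovery can be scored
without re-deriving anything.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: predicted-target error structure correlated
across prediction programs, expression correlation beyond the planted
signal, curated-pathway topology (hubs, bipartite metabolite structure),
non-exponential survival, and informative censoring. Results on synthetic
data certify the machinery and its operating characteristics, not
biological conclusions.

## Numerical choices and degenerate inputs

- p-values are compared at full precision in memory and serialized with six
  significant digits.
- Pairs with zero shared neighbors skip the projection test (P = 1 by
  identity).
- A power-law fit with all counts equal defines R² = 1 when the residuals
  vanish (a horizontal exact fit), 0 otherwise; a two-point fit is exact by
  construction.
- Self-loops in pathway input are dropped with a warning, keeping the gene
  as an isolated node; duplicate edges collapse.
- 2-means refuses an all-identical point cloud; the log-rank test requires
  exactly two non-empty groups; Kaplan–Meier refuses negative times.
- All generator randomness flows from one `numpy` Generator seeded by
  `SimulationConfig.seed`; the same config and seed give a byte-identical
  bundle.

## Problem sizes

The test suite and the acceptance script run everything at two scales,
chosen so a full pass stays comfortably within a desktop budget: a
desk scale (6 pathways × 25 genes, 8 miRNAs, one planted 5-miRNA group —
about 0.1 s per end-to-end replicate, 100 replicates for the recovery rate)
and the study scale (56 miRNAs, 20 × 40-gene pathways, 720 mined
subpathways, 89 patients — about one second per run). Monte-Carlo
calibration uses 2000 null replicates of n = 200 (tests; 1000 in the
acceptance script) and 200 powered replicates of n = 89.

## Known limitations

- The distance-k clique miner and CPM are exact but enumerative; they are
  sized for pathway graphs (tens of genes) and projected networks (tens of
  nodes), not for arbitrary large graphs.
- The observed-nodes projection population degenerates on saturated
  bipartite networks (see above); the pipeline avoids it, but users calling
  `project()` directly on tiny networks should prefer an explicit total.
- Fold-change DEG calling is deliberately simple (no variance model, no
  replicates-aware test) because the chain thresholds fold change only.
- The power-law fit quantifies approximate linearity on log–log points; it
  is not evidence of a generative scale-free mechanism.
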