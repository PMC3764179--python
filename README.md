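# mirsubnet

Network inference for miRNA regulation of pathway sub-regions
("subpathways"), built around the analysis chain used to dissect
miRNA–miRNA interactions in esophageal squamous cell carcinoma: from
per-miRNA target sets and pathway gene graphs to a significance-tested
bipartite miRNA–subpathway network, its one-mode projections, module
structure, and a two-miRNA survival stratification.

It is aimed at computational biologists who have (a) pathway definitions as
gene graphs, (b) predicted miRNA targets with per-predictor support counts,
(c) tumor/normal expression for DEG calling, and (d) optionally a patient
cohort with survival follow-up — or who want to study the method itself on
synthetic data with planted structure, which the package generates.

## The method

1. **Effective targets.** A predicted target is kept when supported by at
   least 4 of the 11 prediction programs; the surviving sets are intersected
   with differentially expressed genes, defined by a tumor/normal
   fold change `mean(T)/mean(N) ≥ 1.5` or `≤ 1/1.5`.
2. **Subpathway mining.** Each pathway is an undirected gene graph; a
   subpathway at distance parameter *k* (default 4) is a *maximal* gene set
   whose pairwise shortest-path distances are all ≤ *k* — equivalently, a
   maximal clique of the graph that joins gene pairs at distance 1..*k*.
3. **Bipartite network.** miRNA → subpathway edges where the miRNA's
   effective targets are over-represented in the subpathway by the
   upper-tail hypergeometric test (*P* < 0.05), split into upregulated and
   downregulated sub-networks by miRNA direction.
4. **Projections.** Two same-mode nodes with neighbor counts *m*, *i* and
   *j* shared neighbors out of a population of *n* are connected when the
   cumulative hypergeometric tail

   P = Σ_{x=j}^{min(m,i)} C(m,x) C(n−m, i−x) / C(n,i)

   is below threshold (*P* < 0.01 for miRNA–miRNA pairs, *P* ≤ 0.001 for
   subpathway–subpathway pairs).
5. **Topology and modules.** Degree distributions are fitted with the
   least-squares power law `y = βx^a` on log–log points (the
   NetworkAnalyzer convention, with its R² and correlation columns), and
   overlapping modules are found by the Clique Percolation Method:
   communities are chains of *k*-cliques sharing *k*−1 nodes.
6. **Survival.** Patients are split by 2-means clustering on the expression
   plane of an interacting miRNA pair and compared with Kaplan–Meier curves
   and the log-rank test.

## Worked example

```python
from mirsubnet import PipelineConfig, SimulationConfig, simulate
from mirsubnet.pipeline import mirna_communities, run_pipeline

bundle = simulate(SimulationConfig(seed=7))      # 56 miRNAs, 89 patients
result = run_pipeline(bundle, PipelineConfig())
print(result.summaries[["network", "nodes", "edges", "r2"]])
print(len(mirna_communities(result, k=4)), "communities at k=4")
```

which prints

```
                       network  nodes  edges        r2
0       mirna-subpathway/total    567   1063  0.764407
1          mirna-subpathway/up    348    509  0.583420
2        mirna-subpathway/down    393    554  0.795556
3            mirna-mirna/total     49    110  0.477893
4               mirna-mirna/up     20     22  0.749932
5             mirna-mirna/down     22     35  0.420111
6  subpathway-subpathway/total    220    562  0.504156
2 communities at k=4
```

— a bipartite network of 1063 significant miRNA–subpathway pairs whose
degree distribution is approximately power-law (R² ≈ 0.76), a total
miRNA–miRNA network with more edges (110) than the up (22) and down (35)
networks combined because pairs of oppositely-directed miRNAs can only
appear there, and two k=4 clique-percolation communities, each containing
one of the generator's planted co-regulation groups.

The numbered scripts under `analysis/` run the same chain step by step
(`python analysis/01_simulate.py`, …) and write their tables under
`results/`; `analysis/08_survival.py` ends with the two-miRNA
stratification (53 vs 36 patients, log-rank χ² = 17.8, p ≈ 2.5e-05 on the
default cohort).

A `mirsubnet` console script exposes each stage on files
(`simulate`, `degs`, `targets`, `mine`, `bipartite`, `project`, `topology`,
`cliques`, `survival`, `run-all`); networks export as TSV, Cytoscape SIF,
or GraphML.

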