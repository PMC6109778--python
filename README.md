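# ruminet

Cross-experiment co-expression analysis of the rumen wall transcriptome,
linking gene clusters to methane-related phenotypes.

Ruminants emit methane (CH4) from microbial fermentation in the rumen, and
the host animal modulates how much: shorter feed mean retention time (MRT,
hours) goes with lower CH4 yield (g CH4 per kg dry matter intake). Bulk
RNA-seq of full-thickness rumen wall biopsies mixes two tissue
compartments — epithelium and smooth muscle — and any single small
experiment is too noisy to tie gene expression to CH4 phenotypes reliably.
`ruminet` implements the cross-experiment strategy for this problem: two
independent sheep experiments (62 animals in four blocks; 24 animals) are
analyzed side by side, and only signals that reproduce in both are kept.

## What it computes

* **PCIT co-expression networks** (from scratch): for every gene trio
  (x, y, z), first-order partial correlations
  `r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))` set a
  local tolerance `eps = mean(|r_xy.z/r_xy|, |r_xz.y/r_xz|, |r_yz.x/r_yz|)`;
  an edge is removed when some third gene dominates it on both sides
  (`|r_xy| < eps |r_xz|` and `|r_xy| < eps |r_yz|`). Surviving pairs with
  `|r| > 0.8` form the network; greedy-modularity communities give the gene
  clusters (muscle, cell cycle, epithelial differentiation, general and
  lipid/oxo-acid metabolism).
* **Between-experiment correlation comparison** by Fisher's Z:
  `z = atanh(r)`, `z_diff = |z_a - z_b| / sqrt(1/(n_a-3) + 1/(n_b-3))`,
  two-sided normal p.
* **Consistent gene selection** with soft cutoffs: per experiment, genes in
  the upper tercile of |r| with a phenotype feed a small PCIT network; a
  gene survives if it is a network node in *both* experiments, with the
  same correlation sign and `|r| >= 0.15` in both.
* **Extreme-MRT differential expression**: the 10 shortest vs 10 longest
  MRT animals, per-gene OLS on log-CPM with
  `y = block + muscle_covariate + MRT_group + e`, where the covariate (mean
  expression of the structural-muscle cluster, or measured muscle depth in
  mm) adjusts for the muscle proportion of the biopsy; Benjamini-Hochberg
  FDR across genes; intersection with the top-200 genes negatively
  correlated with both MRT and CH4 yield.
* **Gene-set overlap and enrichment** by the upper-tail hypergeometric
  probability (`hP`), computed in log space, with BH adjustment.
* A **synthetic two-experiment generator** with planted co-expression
  clusters, tissue-composition mixing, negative-binomial counts and
  phenotype links at configured effect sizes — the test bed for everything
  above.

## Worked example

```python
import ruminet as rn

# Overlap of a 14-gene consistent CH4-yield set with a 73-member
# lipid/oxo-acid metabolism cluster in a 16,011-gene universe:
ot = rn.hypergeometric_overlap(k=8, n_draw=14, K=73, N=16011)
print(f"hP = {ot.hP:.3g}")                  # hP = 3.69e-16

# Are the two experiments' CH4-yield vs intake correlations different?
fz = rn.fisher_z_difference(-0.33, 62, -0.34, 24)
print(f"z_diff = {fz.z_diff:.3f}, p = {fz.p:.3f}")   # z_diff = 0.044, p = 0.965

# Simulate the paired experiments and check a planted link:
counts_a, counts_b, phen_a, phen_b, truth = rn.simulate_pair(rn.SimConfig(seed=1))
table = rn.realized_effects(truth, counts_a, phen_a)
print(table[(table.cluster == "lipid_oxo") & (table.phenotype == "ch4_yield")])
#   cluster  phenotype  r_activity  r_expression   n  undefined
# lipid_oxo  ch4_yield    0.356738      0.329319  62      False
```

The overlap probability says 8-of-14 shared genes could not plausibly
arise by chance; the Fisher-Z p of 0.965 says the two experiments'
yield-intake correlations are statistically indistinguishable; and the
simulated lipid/oxo cluster shows its planted positive correlation with
CH4 yield (target 0.45, attenuated to ~0.36 at the gene-noise level).

The same analyses run from the shell:

```sh
ruminet simulate --seed 1 --out sim/
ruminet all --dir sim/ --seed 1 --out results/
```

which writes edge lists, cluster assignments, correlation/Fisher tables,
consistent gene lists, DE tables, enrichment results and a JSON manifest.

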