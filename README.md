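# ripnet

Statistical and network-ecology analysis of riparian soil microbiomes
under contrasting hydrological regimes. Given an OTU count table, sample
metadata with environmental variables, and hydrological time series,
`ripnet` runs the full comparison workflow used to ask how flow regime
shapes a soil microbial community:

- **alpha diversity** (richness S, Shannon H′ = −Σ pᵢ ln pᵢ, Pielou
  J = H′/ln S) with Kruskal–Wallis group tests;
- **beta diversity**: Bray–Curtis dissimilarity, PCoA, and one-way
  PERMANOVA (pseudo-F, R², permutation p);
- **environment–community linkage**: RDA with permutation-tested
  explained variance, `envfit`-style vector fitting, and simple/partial
  Mantel tests (Pearson r of unfolded distances, 999 permutations);
- **co-occurrence networks** per group: Spearman edges retained at
  |ρ| ≥ 0.6 and p < 0.05, topology metrics, seeded Louvain modules,
  Zi–Pi role classification (module hubs Zi ≥ 2.5, connectors Pi ≥ 0.62),
  natural-connectivity robustness λ̄ = ln((1/N)Σe^{λᵢ}) under random node
  removal, and a t-test comparing decline slopes between networks;
- **hydrological trends**: Theil–Sen slope (median of pairwise slopes)
  with the Mann–Kendall test (tie-corrected, continuity-corrected) and
  coefficients of variation.

A synthetic-data module generates datasets with planted structure —
correlated taxon blocks (ground-truth network modules), a group effect,
environmental variables riding on a shared latent gradient, and trending
noisy series — so every stage can be validated against known truth.
See `docs/methods.md` for models, conventions and caveats.

## Worked example

Simulate a two-river dataset (2 groups × 8 samples × 300 OTUs with three
planted 20-taxon correlation blocks) and run every stage:

```sh
ripnet --seed 7 --out demo simulate --n-taxa 300
printf 'n_perm: 999\nremoval_reps: 50\n' > demo/cfg.txt
ripnet --seed 7 --out demo/results --config demo/cfg.txt \
    all demo/abundance.tsv demo/metadata.tsv --series-file demo/runoff_series.tsv
```

which prints:

```
pipeline complete; artifacts in demo/results
PERMANOVA R2=0.098 p=0.0130
EastRiver: 121 nodes / 535 edges, Q=0.555, robustness slope=-13.6405
WestRiver: 115 nodes / 394 edges, Q=0.604, robustness slope=-5.5202
```

Reading this: the two rivers differ significantly in community
composition (PERMANOVA on Bray–Curtis, R² ≈ 0.10, p ≈ 0.01 — groups
explain ~10% of the dissimilarity variance). Each river's co-occurrence
network retains a few hundred significant Spearman edges among the ~120
prevalent OTUs, with strong module structure (modularity Q > 0.5, as
expected since modules were planted). The robustness slope is the OLS
decline of natural connectivity as a growing fraction of random nodes is
removed; the denser East River network starts from higher connectivity
and loses more of it per removed fraction.

The trend stage recovers the planted hydrological slopes:

```
$ ripnet --out demo/results trend demo/runoff_series.tsv
EastRiver: slope=0.1246/yr *** (p=8.68e-10)
WestRiver: slope=0.1529/yr *** (p=8.68e-10)
```

(true slopes 0.12 and 0.15 units/yr; *** marks Mann–Kendall p < 0.001).

Artifacts written under `demo/results/` include the per-sample diversity
table, PCoA coordinates with eigenvalues, PERMANOVA/RDA/envfit/Mantel
tables, per-group GraphML networks and edge lists (r, p, sign, module,
Zi, Pi, role), robustness curve points with fitted slopes, and the trend
table. All output is deterministic given `--seed`.

The same functionality is available as a library:

```python
from ripnet import SimSpec, simulate_otu_dataset, run_pipeline, PipelineConfig

table, env, truth = simulate_otu_dataset(SimSpec(), seed=7)
bundle = run_pipeline(table, env, PipelineConfig(seed=7))
bundle.permanova.r_squared, bundle.networks["EastRiver"].metrics.modularity
```

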