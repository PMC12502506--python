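# Methods

`ripnet` implements the statistical workflow used to compare riparian soil
microbiomes between two hydrological regimes (a high-flow and a low-flow
river reach): alpha/beta diversity with nonparametric group tests,
environment–community linkage, Spearman co-occurrence networks with module
detection, topological role classification and spectral robustness, and
Theil–Sen/Mann–Kendall trend analysis of hydrological series. This note
records the models, conventions and numerical choices the code commits to.

## Data model and normalization

Abundance tables are taxa × samples integer counts with a phylum label per
taxon and a group label per sample. Relative abundances (columns rescaled
to sum to 1) feed diversity, ordination and correlation; raw counts are
kept for richness. No rarefaction is applied by default. Before network
construction, taxa must be present (count > 0) in at least a fraction
`prevalence_min` (default 0.5) of the group's samples: with 8 composite
samples per river, correlations over rarer taxa are dominated by zeros and
are not interpretable. Setting `prevalence_min = 0` disables the filter.

All randomness flows from one master seed; each stage derives a child seed
by hashing the stage name into a `SeedSequence`, so stages are independent
and the whole pipeline is byte-reproducible (fixed-precision TSV output).

## Diversity and ordination

Shannon diversity H′ = −Σ pᵢ ln pᵢ uses the natural logarithm so that
Pielou evenness J = H′/ln S lies in [0, 1]; J is reported missing when
S < 2. Group differences are tested with the tie-corrected Kruskal–Wallis
H (χ², k−1 df). Bray–Curtis dissimilarity d(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)
is computed on relative abundances; it is bounded in [0, 1] but is not a
metric (the triangle inequality can fail), which is why ordination uses
PCoA rather than a Euclidean embedding of the raw data.

PCoA is classical scaling: B = −½·J·D²·J with J = I − 11ᵀ/n, eigenvectors
scaled by √λ for λ > 0. Negative eigenvalues are reported but excluded
from coordinates; no Lingoes/Cailliez correction is applied by default.
Axis signs are fixed by forcing the largest-magnitude loading positive.

PERMANOVA follows the classical one-way decomposition on squared
dissimilarities, SS_total = Σ_{i<j} d²ᵢⱼ/n and the per-group analogue for
SS_within; pseudo-F = (SS_between/(a−1))/(SS_within/(n−a)); the p-value
counts permuted F ≥ observed under free label permutation (no strata),
with the (1+count)/(1+n_perm) correction. The implementation agrees with
scikit-bio's to ~1e-9 on the statistic (cross-checked in the tests).

## Environment linkage

Environmental dissimilarity is Euclidean distance on z-scored variables
(sample sd, n−1); a constant variable contributes zero distance and is
flagged. Hydrological indices derived from 20-year river averages are
near-constant within a river, and the code warns when a variable has ≤ 2
distinct values.

Mantel tests correlate the unfolded upper triangles with Pearson r;
significance permutes rows+columns of the first matrix jointly, one-sided
(positive association) by default, 999 permutations. The partial Mantel
r_AB·C = (r_AB − r_AC·r_BC)/√((1−r_AC²)(1−r_BC²)) is permuted "raw": the
first matrix is relabeled and the full partial statistic recomputed. The
per-variable linkage table reports, for each variable, the simple Mantel r
against the community distance and the partial r holding the Euclidean
distance on all remaining variables constant.

RDA regresses the column-centered relative-abundance matrix on z-scored
explanatory variables (optional Hellinger transform, off by default);
constrained axes come from the SVD of the fitted values and
total_explained = SS(fitted)/SS(total). The global test permutes rows of
the explanatory matrix and compares pseudo-F. Collinear predictors are
rejected with the offending columns named. Note that with few samples and
several predictors, total_explained is optimistic (it is not adjusted R²);
the permutation p is the guard against over-reading it. `envfit` projects
each variable on the first two ordination axes, reporting direction
cosines, r² and a variable-permutation p.

## Co-occurrence networks

Edges are Spearman correlations over all taxon pairs within one group's
normalized table: average ranks for ties, two-sided p from the
t-approximation t = ρ√((n−2)/(1−ρ²)), retained when |ρ| ≥ 0.6 and
p < 0.05. No multiple-testing correction is applied by default, matching
the stated edge rule; Benjamini–Hochberg is available and logged when
used. |ρ| = 1 is assigned the smallest positive double rather than 0 so
BH remains well defined. Constant taxa are skipped with a log entry.
Graphs are simple and undirected; the signed correlation is an edge
attribute, but modularity, Zi–Pi and spectra all use the unweighted
adjacency (no weighting rule is defensible at n = 8). Isolated nodes are
excluded from the displayed network by default (configurable).

Modules come from seeded Louvain maximization (resolution 1, best of 10
restarts by Q); Q is always re-evaluated with the hand formula
Σ_m (e_mm − a_m²) so the reported value is implementation-independent.
Topological roles use the within-module degree z-score Zi (sd = 0 → Zi = 0)
and among-module connectivity Pi = 1 − Σ_t (k_it/k_i)² with thresholds
Zi = 2.5 and Pi = 0.62: peripherals, connectors, module hubs, network hubs.

## Natural connectivity and robustness

Natural connectivity λ̄ = ln((1/N)·Σ e^{λᵢ}) over adjacency eigenvalues,
computed via `eigvalsh` with a λ_max shift for overflow safety. It is
non-negative for any graph and 0 for an edgeless one. Robustness curves
remove ⌈fN⌉ nodes uniformly at random (without replacement), 100
replicates per fraction over f = 0.05…0.50 in steps of 0.05 by default,
recomputing λ̄ on the induced subgraph with N = the post-removal node
count. The curve summary is the OLS slope of λ̄ on f with R²; two curves
are compared by a two-line regression with a group×fraction interaction
and a two-sided t-test on the interaction coefficient.

A caveat that matters when reading slopes: λ̄ scales with network size and
density (λ̄(K_n) ≈ n − 1 − ln n, whereas any tree has a bounded spectrum),
so a dense graph's absolute — and even relative λ̄/λ̄₀ — decline per
removed fraction is steeper than a sparse one's. Slope comparisons are
therefore meaningful between networks of comparable size and connectivity
scale (as in the per-group networks this pipeline builds), not between
extremes such as a complete graph and a spanning tree. The robustness unit
tests document this measured ordering explicitly.

## Hydrological trends

The Theil–Sen slope is the median of all n(n−1)/2 pairwise slopes, with
intercept median(y − βt); it tolerates up to ~29% outliers. Mann–Kendall
uses S = Σ_{i<j} sgn(y_j − y_i), tie-corrected variance
[n(n−1)(2n+5) − Σ t_k(t_k−1)(2t_k+5)]/18, continuity-corrected Z and a
two-sided normal p. Significance is rendered as *, **, *** at 0.05, 0.01,
0.001. The coefficient of variation is the sample (n−1) sd over the mean
and errors on non-positive means. No pre-whitening for serial correlation
is applied; for strongly autocorrelated series the MK test is anti-
conservative (known caveat).

## Synthetic data

The generator emulates the field design at desk scale: 2 river groups ×
8 composite samples, 300 OTUs, mean library size 20,000. Counts follow a
Gaussian copula: a latent multivariate normal with block-diagonal
correlation (three planted 20-taxon blocks at ρ = 0.8 by default; the
blocks are the ground-truth network modules) is pushed through lognormal
marginals — base abundance N(0, 1.5²) on the log scale, within-sample
fluctuation `latent_scale` = 2 log-units, realistic for amplicon data —
then closed to compositions and sampled as Dirichlet-multinomial counts
(concentration 200) at Poisson-varying depth. Planted-block taxa draw
their base abundance from the prevalent stratum (N(1.0, 0.5²)): planted
co-occurrence is only observable among taxa present in most samples, and
rare members would be removed by the prevalence filter before the network
stage either way.

A latent gradient (signed group axis + within-group N(0, 0.5²)) shifts a
designated set of background taxa and simultaneously feeds every
environmental variable through per-variable loadings — this shared
construction is what gives the partial Mantel test a known confounder to
remove. The truth record (block labels, affected taxa, per-sample
gradient, loadings) suffices to score every recovery test. Hydrological
series are y_t = a + βt + N(0, σ²).

What the generator does not emulate: spatial autocorrelation among plots,
taxon-specific sequencing biases, zero-inflation beyond what the
compositional-count construction produces, and non-monotone taxon–gradient
responses. Passing recovery tests therefore show the estimators work when
their assumptions hold, not that real riparian data satisfy them.

## Problem sizes used in the checks

Oracle and calibration checks are sized to run on one CPU in a few
minutes: 100 random graphs (n ≤ 12) for the spectral oracle, 50 planted
two-block graphs for module recovery, 100 seeds × 50 replicates for
robustness orderings, 2000 null simulations with 199 permutations for each
type-I-error calibration, 500 replicates for trend recovery, and one full
pipeline run at the default 2 × 8 × 300 design.
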