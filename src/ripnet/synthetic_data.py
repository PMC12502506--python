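"""Synthetic data with planted structure for every pipeline stage.

The generator emulates a two-river riparian sampling design at desk scale:
two groups of composite soil samples (8 per group by default), overdispersed
compositional OTU counts whose rank structure carries planted correlation
blocks (the future network modules), environmental variables partially
collinear with a latent community gradient, and noisy linearly trending
annual hydrological series.

Construction is a Gaussian copula: a latent multivariate normal with
block-diagonal correlation supplies the ranks; a lognormal marginal per
taxon turns latent scores into abundance propensities; compositions are
converted to counts by a Dirichlet-multinomial, giving the overdispersion
typical of amplicon libraries.  Because the downstream pipeline consumes
only ranks (Spearman) and compositions (Bray-Curtis), any marginal with the
right rank structure suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import TAXONOMY_COLUMN, AbundanceTable, EnvTable, ValidationError


@dataclass
class EnvVariableSpec:
    """One simulated environmental variable.

    ``group_means`` gives the deterministic offset per group; ``loading``
    couples the variable to the latent community gradient (shared across
    variables, which is what makes them partially collinear); ``sd`` is
    iid measurement noise.
    """

    name: str
    group_means: tuple[float, ...] = (0.0, 0.0)
    sd: float = 1.0
    loading: float = 0.0


DEFAULT_ENV_SPECS: tuple[EnvVariableSpec, ...] = (
    # Soil variables: group contrast plus gradient loading, mixed units.
    EnvVariableSpec("SOM", (12.0, 9.0), 1.5, 0.8),
    EnvVariableSpec("BD", (1.35, 1.50), 0.05, -0.04),
    EnvVariableSpec("AN", (40.0, 30.0), 4.0, 3.0),
    EnvVariableSpec("AP", (6.0, 5.0), 0.8, 0.4),
    EnvVariableSpec("AK", (110.0, 100.0), 10.0, 2.0),
    EnvVariableSpec("sand", (55.0, 70.0), 5.0, -4.0),
    EnvVariableSpec("silt", (30.0, 20.0), 4.0, 3.0),
    EnvVariableSpec("clay", (15.0, 10.0), 2.0, 1.0),
    # Hydrological indices: 20-year averages differ by river, so they are
    # near-constant within a group (the pipeline warns about this).
    EnvVariableSpec("runoff", (10.5, 5.0), 0.2, 0.1),
    EnvVariableSpec("Wa", (80.0, 35.0), 1.0, 0.5),
    EnvVariableSpec("SeasonCV", (0.67, 0.37), 0.02, 0.0),
)


@dataclass
class SimSpec:
    """Parameters of the synthetic riparian microbiome dataset.

    Defaults mirror the field design the pipeline targets: 2 river groups
    with 8 composite plots each, 300 OTUs of which three blocks of 20 share
    a strong within-block latent correlation (0.8), a weak background
    correlation between blocks, mean library size 20,000 with
    Dirichlet-multinomial overdispersion, and 11 environmental variables
    riding on one latent gradient.
    """

    n_groups: int = 2
    n_samples_per_group: int = 8
    n_taxa: int = 300
    block_structure: tuple[tuple[int, float], ...] = ((20, 0.8), (20, 0.8), (20, 0.8))
    rho_between: float = 0.0
    sequencing_depth: float = 20_000.0
    dispersion: float = 200.0  # Dirichlet concentration; larger = less overdispersed
    group_effect_taxa: int = 30
    group_effect_size: float = 1.0  # shift of log-propensity per unit gradient
    gradient_sd: float = 0.5  # within-group spread of the latent gradient
    latent_scale: float = 2.0  # sd of log-abundance fluctuation across samples
    env_specs: tuple[EnvVariableSpec, ...] = DEFAULT_ENV_SPECS
    n_phyla: int = 8

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_samples_per_group < 2:
            raise ValidationError("need >=1 group with >=2 samples each")
        if sum(b for b, _ in self.block_structure) > self.n_taxa:
            raise ValidationError("block sizes exceed n_taxa")
        for _, rho in self.block_structure:
            if not -1 < rho < 1:
                raise ValidationError("within-block correlation must be in (-1, 1)")
        if not -1 < self.rho_between < 1:
            raise ValidationError("between-block correlation must be in (-1, 1)")
        if self.sequencing_depth <= 0 or self.dispersion <= 0:
            raise ValidationError("depth and dispersion must be positive")


def latent_correlation(spec: SimSpec) -> np.ndarray:
    """Block-diagonal latent correlation matrix implied by the spec.

    Raises before sampling if the matrix is not positive definite.
    """
    p = spec.n_taxa
    corr = np.full((p, p), spec.rho_between)
    start = 0
    for size, rho_in in spec.block_structure:
        corr[start : start + size, start : start + size] = rho_in
        start += size
    np.fill_diagonal(corr, 1.0)
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("latent correlation matrix is not positive definite") from exc
    return corr


def block_labels(spec: SimSpec) -> np.ndarray:
    """Planted block id per taxon; -1 for background taxa."""
    labels = np.full(spec.n_taxa, -1)
    start = 0
    for b, (size, _) in enumerate(spec.block_structure):
        labels[start : start + size] = b
        start += size
    return labels


PHYLA = (
    "Proteobacteria", "Actinobacteria", "Acidobacteria", "Chloroflexi",
    "Bacteroidetes", "Gemmatimonadetes", "Firmicutes", "Ascomycota",
    "Basidiomycota", "Euryarchaeota", "Thaumarchaeota", "Unclassified",
)


def simulate_otu_dataset(
    spec: SimSpec, seed: int
) -> tuple[AbundanceTable, EnvTable, dict]:
    """Draw one synthetic dataset.

    Returns the abundance table, the environmental table and a truth
    record holding everything a recovery test needs: planted block
    membership, the group-affected taxa, each sample's latent gradient
    score and the environmental loadings.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_groups * spec.n_samples_per_group
    p = spec.n_taxa

    corr = latent_correlation(spec)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, p)) @ chol.T  # latent scores, samples x taxa

    group_idx = np.repeat(np.arange(spec.n_groups), spec.n_samples_per_group)
    group_names = [f"G{g + 1}" for g in range(spec.n_groups)]
    if spec.n_groups == 2:
        group_names = ["EastRiver", "WestRiver"]

    # Latent community gradient: a signed group axis plus within-group
    # spread.  It shifts the affected taxa AND feeds the environmental
    # variables, creating known confounding for partial-Mantel tests.
    group_axis = np.linspace(-1, 1, spec.n_groups) if spec.n_groups > 1 else np.zeros(1)
    gradient = group_axis[group_idx] + rng.normal(0.0, spec.gradient_sd, n)

    # Taxon base abundances: lognormal rank-abundance curve.  Planted-block
    # members are drawn from the prevalent stratum (narrower, higher mean):
    # co-occurrence modules are a property of taxa abundant enough to be
    # observed in most samples, and this keeps them past prevalence filters.
    base_log = rng.normal(0.0, 1.5, p)
    labels = block_labels(spec)
    in_block = labels >= 0
    base_log[in_block] = rng.normal(1.0, 0.5, in_block.sum())
    bg = np.flatnonzero(labels == -1)
    n_affected = min(spec.group_effect_taxa, bg.size)
    affected = rng.choice(bg, size=n_affected, replace=False) if n_affected else np.array([], int)

    # lognormal marginal preserves the copula's ranks; latent_scale sets the
    # size of biological variation relative to counting noise
    log_prop = base_log[None, :] + spec.latent_scale * z
    log_prop[:, affected] += spec.group_effect_size * gradient[:, None]
    prop = np.exp(log_prop)
    comp = prop / prop.sum(axis=1, keepdims=True)

    # Dirichlet-multinomial counts at Poisson-varying library size.
    depth = rng.poisson(spec.sequencing_depth, n)
    counts = np.empty((n, p), dtype=np.int64)
    for i in range(n):
        theta = rng.dirichlet(comp[i] * spec.dispersion)
        counts[i] = rng.multinomial(depth[i], theta)

    taxon_ids = [f"OTU_{i + 1}" for i in range(p)]
    sample_ids = [f"{group_names[g]}_{j + 1}" for g in range(spec.n_groups)
                  for j in range(spec.n_samples_per_group)]
    # Phylum labels: one phylum per planted block, background taxa random.
    phyla = np.array(PHYLA)[rng.integers(0, min(spec.n_phyla, len(PHYLA)), p)]
    for b in range(len(spec.block_structure)):
        phyla[labels == b] = PHYLA[b % len(PHYLA)]

    table = AbundanceTable(
        counts=pd.DataFrame(counts.T, index=taxon_ids, columns=sample_ids),
        taxonomy=pd.Series(phyla, index=taxon_ids, name=TAXONOMY_COLUMN),
        groups=pd.Series([group_names[g] for g in group_idx], index=sample_ids, name="group"),
    )

    env_data = {}
    for v in spec.env_specs:
        means = np.asarray(v.group_means, float)
        if means.size < spec.n_groups:
            means = np.resize(means, spec.n_groups)
        env_data[v.name] = (
            means[group_idx] + v.loading * gradient + rng.normal(0.0, v.sd, n)
        )
    env = EnvTable(pd.DataFrame(env_data, index=sample_ids))

    truth = {
        "seed": int(seed),
        "block_labels": {t: int(b) for t, b in zip(taxon_ids, labels)},
        "group_affected_taxa": [taxon_ids[i] for i in affected],
        "gradient": {s: float(g) for s, g in zip(sample_ids, gradient)},
        "env_loadings": {v.name: float(v.loading) for v in spec.env_specs},
        "groups": {s: group_names[g] for s, g in zip(sample_ids, group_idx)},
    }
    return table, env, truth


def simulate_trend_series(
    n_years: int,
    beta_true: float,
    sigma: float,
    seed: int,
    intercept: float = 0.0,
    start_year: int = 2000,
) -> pd.DataFrame:
    """Linear trend plus iid Gaussian noise: y_t = a + beta*t + eps_t."""
    if n_years < 3:
        raise ValidationError("need at least 3 years for trend analysis")
    if sigma < 0:
        raise ValidationError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(n_years, dtype=float)
    y = intercept + beta_true * t + rng.normal(0.0, sigma, n_years)
    return pd.DataFrame({"year": (start_year + t).astype(int), "value": y})
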