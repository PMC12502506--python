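"""Alpha diversity, Bray-Curtis dissimilarity, PCoA and PERMANOVA.

Shannon entropy uses the natural logarithm so that Pielou evenness is
J = H'/ln S.  PCoA is classical scaling (Gower double-centering); negative
eigenvalues are reported but excluded from the coordinates, with no
Lingoes/Cailliez correction by default.  PERMANOVA permutes sample labels
freely (no strata), matching an unrestricted two-group design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AbundanceTable, ValidationError


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample richness S, Shannon H' (nats) and Pielou evenness J.

    J = H'/ln S is undefined (NaN) for samples with fewer than 2 taxa.
    """
    x = table.counts.to_numpy(dtype=float)
    totals = x.sum(axis=0)
    if (totals <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValidationError(f"empty samples: {bad}")
    p = x / totals
    richness = (x > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=0)
        evenness = np.where(richness >= 2, shannon / np.log(richness), np.nan)
    return pd.DataFrame(
        {
            "richness": richness,
            "shannon": shannon,
            "evenness": evenness,
            "group": table.groups.to_numpy(),
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def kruskal_wallis(values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray):
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValidationError("empty group in Kruskal-Wallis input")
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


def bray_curtis(table: AbundanceTable, relative: bool = True) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples,
    d(i,j) = sum|x_i - x_j| / sum(x_i + x_j), on relative abundances
    by default.  Bounded in [0, 1]; not a metric (triangle inequality
    can fail), which is why downstream ordination is PCoA."""
    x = table.counts.to_numpy(dtype=float).T  # samples x taxa
    if relative:
        totals = x.sum(axis=1, keepdims=True)
        if (totals <= 0).any():
            raise ValidationError("cannot normalize zero-sum sample")
        x = x / totals
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(d, 0.0)
    ids = pd.Index(table.sample_ids, name="sample_id")
    return pd.DataFrame(d, index=ids, columns=ids)


def _check_distance(d: pd.DataFrame) -> np.ndarray:
    a = d.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(a), 0.0, atol=1e-10):
        raise ValidationError("distance matrix must have zero diagonal")
    return a


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes, scaled by sqrt(lambda)
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing (negatives kept)
    proportion_explained: np.ndarray  # lambda_k / sum(positive lambda)


def pcoa(d: pd.DataFrame) -> OrdinationResult:
    """Classical scaling: B = -1/2 J D^2 J with J = I - 11'/n, then
    eigendecomposition; coordinates are eigenvectors scaled by sqrt(lambda)
    for positive eigenvalues.  Axis signs are fixed by forcing the
    largest-magnitude loading on each axis positive."""
    a = _check_distance(d)
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (a**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * abs(evals[0])) if n else 0.0
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):  # deterministic sign convention
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] *= -1
    pos_sum = evals[pos].sum()
    prop = np.where(evals > 0, evals / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    cols = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=d.index, columns=cols),
        eigenvalues=evals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_perm: int
    n_groups: int
    n_samples: int


def _permanova_ss(d2: np.ndarray, group_codes: np.ndarray, n_groups: int):
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(group_codes == g)
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_total, ss_within


def permanova(
    d: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d2_ij / n; SS_within sums the analogous term per
    group; pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)); the p-value
    counts permuted pseudo-F >= observed under whole-sample label
    shuffling, with the +1 correction.
    """
    a = _check_distance(d)
    groups = np.asarray(groups)
    if groups.shape[0] != a.shape[0]:
        raise ValidationError("group labels must match distance matrix samples")
    labels, codes = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = labels[sizes < 2].tolist()
        raise ValidationError(f"groups of size 1 not allowed: {small}")
    n = a.shape[0]
    d2 = a**2
    ss_total, ss_within = _permanova_ss(d2, codes, k)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (k - 1)) / (ss_within / (n - k))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        ss_t, ss_w = _permanova_ss(d2, perm, k)
        f_perm = ((ss_t - ss_w) / (k - 1)) / (ss_w / (n - k)) if ss_w > 0 else np.inf
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm, k, n)
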