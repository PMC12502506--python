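"""Environment-community association: Mantel tests, RDA, envfit.

Environmental dissimilarity is Euclidean distance on z-scored variables,
the standard choice for mixed-unit soil and hydrology measurements.
Mantel tests use Pearson correlation of the unfolded upper triangles, with
one-sided (positive-association) permutation p-values by default, matching
ecological convention.  The partial Mantel permutes the first matrix and
recomputes the partial statistic ("raw" permutation scheme).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import AbundanceTable, EnvTable, ValidationError
from .diversity import OrdinationResult, _check_distance


def env_distance(
    env: EnvTable, variables: Sequence[str] | None = None, scale: bool = True
) -> pd.DataFrame:
    """Euclidean distance between samples on the selected (z-scored)
    environmental variables; a single variable gives |z_i - z_j|."""
    variables = variables if variables is not None else env.variables
    x = env.select(variables).to_numpy(dtype=float)
    if scale:
        sd = x.std(axis=0, ddof=1)
        mean = x.mean(axis=0)
        # constant columns contribute zero distance rather than NaN
        x = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    ids = pd.Index(env.sample_ids, name="sample_id")
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    n_samples: int
    controlled: str | None = None  # label of the held-constant matrix


def _aligned(dA: pd.DataFrame, dB: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if list(dA.index) != list(dB.index):
        if set(dA.index) != set(dB.index):
            raise ValidationError("Mantel matrices have different sample sets")
        dB = dB.loc[dA.index, dA.index]
    return _check_distance(dA), _check_distance(dB)


def _upper(a: np.ndarray) -> np.ndarray:
    return a[np.triu_indices(a.shape[0], 1)]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt((xc**2).sum()), np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValidationError("zero variance in distance vector")
    return float((xc * yc).sum() / (sx * sy))


def mantel(
    dA: pd.DataFrame,
    dB: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Simple Mantel test: Pearson r of the unfolded upper triangles,
    permutation p by jointly relabeling rows+columns of the first matrix."""
    a, b = _aligned(dA, dB)
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    r_obs = _pearson(a[iu], b[iu])
    rng = np.random.default_rng(seed)
    vb = b[iu]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _pearson(a[np.ix_(perm, perm)][iu], vb)
        if alternative == "greater":
            hit = r_p >= r_obs
        elif alternative == "two-sided":
            hit = abs(r_p) >= abs(r_obs)
        else:
            raise ValidationError(f"unknown alternative {alternative!r}")
        count += hit
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r_obs, float(p), n_perm, n)


def _partial_r(rab: float, rac: float, rbc: float) -> float:
    den = np.sqrt((1 - rac**2) * (1 - rbc**2))
    if den < 1e-12:
        raise ValidationError("control matrix collinear with response")
    return (rab - rac * rbc) / den


def partial_mantel(
    dA: pd.DataFrame,
    dB: pd.DataFrame,
    dC: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    controlled: str | None = None,
) -> MantelResult:
    """Partial Mantel: correlation of dA and dB controlling dC,
    r_AB.C = (r_AB - r_AC r_BC) / sqrt((1-r_AC^2)(1-r_BC^2)); the p-value
    permutes dA and recomputes the partial statistic."""
    a, b = _aligned(dA, dB)
    _, c = _aligned(dA, dC)
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    vb, vc = b[iu], c[iu]
    rbc = _pearson(vb, vc)
    r_obs = _partial_r(_pearson(a[iu], vb), _pearson(a[iu], vc), rbc)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ap = a[np.ix_(perm, perm)][iu]
        r_p = _partial_r(_pearson(ap, vb), _pearson(ap, vc), rbc)
        if alternative == "greater":
            hit = r_p >= r_obs
        elif alternative == "two-sided":
            hit = abs(r_p) >= abs(r_obs)
        else:
            raise ValidationError(f"unknown alternative {alternative!r}")
        count += hit
    p = (1 + count) / (n_perm + 1)
    return MantelResult(float(r_obs), float(p), n_perm, n, controlled=controlled)


def mantel_table(
    d_community: pd.DataFrame,
    env: EnvTable,
    variables: Sequence[str] | None = None,
    control: Sequence[str] | str = "rest",
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-variable simple and partial Mantel tests against a community
    distance matrix.  With ``control='rest'`` each variable's partial test
    holds the Euclidean distance on all remaining variables constant."""
    variables = list(variables if variables is not None else env.variables)
    rows = []
    for i, v in enumerate(variables):
        dv = env_distance(env, [v])
        simple = mantel(d_community, dv, n_perm=n_perm, seed=seed + i)
        row = {"variable": v, "mantel_r": simple.r, "mantel_p": simple.p_value}
        others = [w for w in variables if w != v] if control == "rest" else list(control)
        if others:
            dc = env_distance(env, others)
            try:
                part = partial_mantel(
                    d_community, dv, dc, n_perm=n_perm, seed=seed + i,
                    controlled=",".join(others),
                )
                row["partial_r"], row["partial_p"] = part.r, part.p_value
            except ValidationError:
                row["partial_r"], row["partial_p"] = np.nan, np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("variable")
    out["n_perm"] = n_perm
    return out


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------


@dataclass
class RdaResult:
    site_scores: pd.DataFrame  # samples x constrained axes
    biplot_vectors: pd.DataFrame  # variables x constrained axes (correlations)
    eigenvalues: np.ndarray  # of constrained axes
    axis_proportions: np.ndarray  # per-axis share of total community variance
    total_explained: float  # SS(fitted)/SS(total)
    pseudo_f: float
    p_value: float
    n_perm: int


def _rda_decompose(y: np.ndarray, x: np.ndarray):
    """Centered response y regressed on centered predictors x; returns
    (fitted, ss_fit, ss_total)."""
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ coef
    return fitted, float((fitted**2).sum()), float((y**2).sum())


def rda_fit(
    table: AbundanceTable,
    env: EnvTable,
    variables: Sequence[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    hellinger: bool = False,
) -> RdaResult:
    """Redundancy analysis: the community matrix (relative abundances,
    column-centered; optional Hellinger transform) is regressed on the
    z-scored explanatory variables; constrained axes come from the SVD of
    the fitted values; total_explained = SS(fitted)/SS(total); the global
    permutation test shuffles rows of the explanatory matrix."""
    variables = list(variables if variables is not None else env.variables)
    env = env.align_to(table)
    xraw = env.select(variables).to_numpy(dtype=float)
    n, m = xraw.shape
    if n <= m + 1:
        raise ValidationError(f"need n_samples > n_vars + 1 ({n} samples, {m} variables)")
    sd = xraw.std(axis=0, ddof=1)
    if (sd == 0).any():
        const = [v for v, s in zip(variables, sd) if s == 0]
        raise ValidationError(f"constant explanatory variables: {const}")
    x = (xraw - xraw.mean(axis=0)) / sd
    if np.linalg.matrix_rank(x, tol=1e-8 * max(n, m)) < m:
        # name the columns that add no rank
        dep = []
        for j in range(1, m):
            if np.linalg.matrix_rank(x[:, : j + 1], tol=1e-8 * n) <= np.linalg.matrix_rank(
                x[:, :j], tol=1e-8 * n
            ):
                dep.append(variables[j])
        raise ValidationError(f"collinear explanatory variables: {dep or variables}")

    yraw = table.counts.to_numpy(dtype=float).T  # samples x taxa
    totals = yraw.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValidationError("zero-sum sample in community matrix")
    yrel = yraw / totals
    if hellinger:
        yrel = np.sqrt(yrel)
    y = yrel - yrel.mean(axis=0)

    fitted, ss_fit, ss_total = _rda_decompose(y, x)
    if ss_total == 0:
        raise ValidationError("community matrix has zero variance")
    total_explained = ss_fit / ss_total
    ss_res = ss_total - ss_fit
    dof_res = n - m - 1
    f_obs = (ss_fit / m) / (ss_res / dof_res) if ss_res > 0 and dof_res > 0 else np.inf

    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    evals = (s**2) / (n - 1)
    k = min(m, int((s > 1e-10 * max(s[0], 1.0)).sum())) if s.size else 0
    scores = u[:, :k] * s[:k]
    for j in range(k):  # deterministic axis sign
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] *= -1
    # biplot arrows: correlation of each z-scored variable with axis scores
    biplot = np.zeros((m, k))
    for j in range(k):
        sj = scores[:, j]
        denom = np.sqrt((sj**2).sum() * (x**2).sum(axis=0))
        with np.errstate(invalid="ignore"):
            biplot[:, j] = np.where(denom > 0, (x * sj[:, None]).sum(axis=0) / denom, 0.0)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        xp = x[rng.permutation(n)]
        _, ss_fit_p, _ = _rda_decompose(y, xp)
        ss_res_p = ss_total - ss_fit_p
        f_p = (ss_fit_p / m) / (ss_res_p / dof_res) if ss_res_p > 0 else np.inf
        if f_p >= f_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)

    axes = [f"RDA{j + 1}" for j in range(k)]
    return RdaResult(
        site_scores=pd.DataFrame(scores, index=table.sample_ids, columns=axes),
        biplot_vectors=pd.DataFrame(biplot, index=variables, columns=axes),
        eigenvalues=evals[:k],
        axis_proportions=(s[:k] ** 2) / ((y**2).sum()) if k else np.zeros(0),
        total_explained=float(total_explained),
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# envfit
# ---------------------------------------------------------------------------


def envfit(
    ordination: OrdinationResult,
    env: EnvTable,
    variables: Sequence[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    n_axes: int = 2,
) -> pd.DataFrame:
    """Vector fitting of environmental variables onto ordination axes.

    Each variable is regressed on the first ``n_axes`` ordination axes;
    reported are the direction cosines of the fitted vector, the squared
    correlation r2, and a permutation p obtained by shuffling the variable
    across samples.
    """
    variables = list(variables if variables is not None else env.variables)
    coords = ordination.coordinates.to_numpy(dtype=float)
    if coords.shape[1] < n_axes:
        raise ValidationError(f"ordination has fewer than {n_axes} axes")
    sc = coords[:, :n_axes]
    sc = sc - sc.mean(axis=0)
    n = sc.shape[0]
    # hat-matrix-free projection via QR of the axis scores
    q, _ = np.linalg.qr(sc)
    env_data = env.select(variables).to_numpy(dtype=float)
    if env_data.shape[0] != n:
        raise ValidationError("environmental table does not match ordination samples")
    rng = np.random.default_rng(seed)
    rows = []
    for j, name in enumerate(variables):
        v = env_data[:, j] - env_data[:, j].mean()
        ss_v = (v**2).sum()
        if ss_v == 0:
            rows.append({"variable": name, "r2": np.nan, "p": np.nan,
                         **{f"cos{k+1}": np.nan for k in range(n_axes)}})
            continue
        proj = q.T @ v
        r2_obs = float((proj**2).sum() / ss_v)
        coef, *_ = np.linalg.lstsq(sc, v, rcond=None)
        norm = np.linalg.norm(coef)
        cosines = coef / norm if norm > 0 else np.zeros(n_axes)
        count = 0
        for _ in range(n_perm):
            vp = v[rng.permutation(n)]
            if ((q.T @ vp) ** 2).sum() / ss_v >= r2_obs:
                count += 1
        p = (1 + count) / (n_perm + 1)
        rows.append({"variable": name, "r2": r2_obs, "p": float(p),
                     **{f"cos{k+1}": float(c) for k, c in enumerate(cosines)}})
    return pd.DataFrame(rows).set_index("variable")
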