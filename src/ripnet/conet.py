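"""Co-occurrence networks: Spearman edge screening, topology metrics,
module detection, Zi-Pi role classification, and natural-connectivity
robustness under random node removal.

Edges are significant Spearman correlations between taxa (|rho| >= r_min,
p < alpha by default, mirroring the |r| >= 0.6, p < 0.05 rule common in
microbiome network studies).  Graphs are simple and undirected; the signed
correlation is kept as an edge attribute but all spectral and modularity
computations use the unweighted adjacency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AbundanceTable, ValidationError

logger = logging.getLogger("ripnet")

# Role thresholds in the Zi-Pi plane: within-module degree z-score 2.5,
# among-module connectivity 0.62.
ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


# ---------------------------------------------------------------------------
# Edge screening
# ---------------------------------------------------------------------------


def spearman_filtered(
    table: AbundanceTable,
    r_min: float = 0.6,
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """Score every unordered taxon pair by Spearman correlation and keep
    pairs with |rho| >= r_min and (optionally BH-corrected) p < alpha.

    rho uses average ranks for ties; p comes from the t approximation
    t = rho * sqrt((n-2)/(1-rho^2)), two-sided.  |rho| = 1 is assigned the
    smallest positive float so BH correction stays well defined.  Constant
    taxa are skipped (rho undefined) with a log entry.
    """
    n = table.n_samples
    if n < 4:
        raise ValidationError(f"need >= 4 samples for correlation screening, got {n}")
    if n < 10:
        logger.warning("only %d samples: correlation estimates are noisy", n)
    if correction not in ("none", "BH"):
        raise ValidationError(f"unknown correction {correction!r}")

    x = table.counts.to_numpy(dtype=float)
    const = x.std(axis=1) == 0
    if const.any():
        for t in np.asarray(table.taxon_ids)[const]:
            logger.info("taxon %s constant across samples; pairs skipped", t)
    ids = np.asarray(table.taxon_ids)[~const]
    ranks = np.apply_along_axis(stats.rankdata, 1, x[~const])  # average ranks

    rc = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((rc**2).sum(axis=1))
    rho = (rc @ rc.T) / np.outer(norm, norm)
    np.clip(rho, -1.0, 1.0, out=rho)

    iu, ju = np.triu_indices(len(ids), 1)
    r = rho[iu, ju]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t_stat), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, np.finfo(float).tiny, p)

    edges = pd.DataFrame(
        {
            "source": ids[iu],
            "target": ids[ju],
            "spearman_r": r,
            "p": p,
        }
    )
    keep_r = np.abs(edges["spearman_r"]) >= r_min
    if correction == "BH":
        edges["p_adj"] = _benjamini_hochberg(edges["p"].to_numpy())
        keep_p = edges["p_adj"] < alpha
    else:
        keep_p = edges["p"] < alpha
    out = edges[keep_r & keep_p].reset_index(drop=True)
    out["sign"] = np.where(out["spearman_r"] >= 0, "+", "-")
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


# ---------------------------------------------------------------------------
# Graph construction and metrics
# ---------------------------------------------------------------------------


def build_network(
    edges: pd.DataFrame,
    taxonomy: pd.Series | None = None,
    nodes: list | None = None,
) -> nx.Graph:
    """Assemble the co-occurrence graph from an edge candidate table.

    Self-loops are dropped; duplicate pairs keep the first record with a
    warning.  Isolated taxa are excluded unless explicitly passed via
    ``nodes``; node attributes are phylum (if taxonomy given) and degree.
    """
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for row in edges.itertuples(index=False):
        u, v = row.source, row.target
        if u == v:
            logger.warning("self-loop on %s dropped", u)
            continue
        if g.has_edge(u, v):
            logger.warning("duplicate edge %s-%s; keeping first record", u, v)
            continue
        g.add_edge(
            u, v,
            spearman_r=float(row.spearman_r),
            p=float(row.p),
            sign=getattr(row, "sign", "+" if row.spearman_r >= 0 else "-"),
        )
    if taxonomy is not None:
        nx.set_node_attributes(
            g, {n: str(taxonomy.get(n, "Unclassified")) for n in g.nodes}, "phylum"
        )
    nx.set_node_attributes(g, dict(g.degree()), "degree")
    return g


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    average_degree: float
    clustering: float  # mean local clustering, 0 for degree < 2 nodes
    modularity: float | None  # Q of the detected partition (None if empty)
    density: float
    positive_fraction: float | None

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "average_degree": self.average_degree,
            "clustering": self.clustering,
            "modularity": self.modularity,
            "density": self.density,
            "positive_fraction": self.positive_fraction,
        }


def network_metrics(g: nx.Graph, modularity: float | None = None) -> NetworkMetrics:
    """Basic topology summary: node/edge counts, average degree 2E/N,
    mean local clustering, density 2E/(N(N-1)), positive-edge fraction."""
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return NetworkMetrics(0, 0, 0.0, 0.0, modularity, 0.0, None)
    avg_deg = 2 * e / n
    clustering = float(np.mean(list(nx.clustering(g).values())))
    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    signs = [d.get("sign") for _, _, d in g.edges(data=True)]
    pos = sum(s == "+" for s in signs)
    pos_frac = pos / e if e > 0 and all(s is not None for s in signs) else None
    return NetworkMetrics(n, e, avg_deg, clustering, modularity, density, pos_frac)


# ---------------------------------------------------------------------------
# Modules and Zi-Pi
# ---------------------------------------------------------------------------


def modularity_q(g: nx.Graph, partition: dict) -> float:
    """Newman modularity Q = sum_m (e_mm - a_m^2) on the unweighted graph,
    where e_mm is the fraction of edges inside module m and a_m the
    fraction of edge ends attached to it."""
    e = g.number_of_edges()
    if e == 0:
        raise ValidationError("modularity undefined for a graph without edges")
    modules = set(partition.values())
    q = 0.0
    for m in modules:
        members = {n for n, mm in partition.items() if mm == m}
        internal = sum(1 for u, v in g.edges if u in members and v in members)
        degree_sum = sum(d for _, d in g.degree(members))
        q += internal / e - (degree_sum / (2 * e)) ** 2
    return q


def detect_modules(g: nx.Graph, seed: int = 0, restarts: int = 10):
    """Seeded Louvain modularity maximization (resolution 1), best of
    ``restarts`` runs by Q.  Returns (node -> module id, Q); an empty
    graph gives ({}, None)."""
    if g.number_of_nodes() == 0:
        return {}, None
    if g.number_of_edges() == 0:
        return {n: i for i, n in enumerate(g.nodes)}, None
    best_part, best_q = None, -np.inf
    for r in range(restarts):
        comms = nx.community.louvain_communities(g, resolution=1.0, seed=seed + r)
        part = {n: i for i, c in enumerate(comms) for n in c}
        q = modularity_q(g, part)
        if q > best_q:
            best_part, best_q = part, q
    return best_part, float(best_q)


def zipi_roles(g: nx.Graph, modules: dict) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and among-module connectivity
    (Pi) per node, with role classification.

    Zi standardizes a node's within-module degree against its module
    members (sd = 0 -> Zi = 0).  Pi = 1 - sum_t (k_it/k_i)^2 over modules
    t; isolated nodes get Pi = 0.  Roles: peripheral (Zi < 2.5, Pi < 0.62),
    connector (Zi < 2.5, Pi >= 0.62), module hub (Zi >= 2.5, Pi < 0.62),
    network hub (Zi >= 2.5, Pi >= 0.62).
    """
    if set(g.nodes) - set(modules):
        raise ValidationError("every node needs a module assignment")
    within = {}
    per_module_links = {}
    for node in g.nodes:
        m = modules[node]
        counts: dict = {}
        for nb in g.neighbors(node):
            counts[modules[nb]] = counts.get(modules[nb], 0) + 1
        within[node] = counts.get(m, 0)
        per_module_links[node] = counts

    module_members: dict = {}
    for node, m in modules.items():
        if node in g.nodes:
            module_members.setdefault(m, []).append(node)

    rows = []
    for node in g.nodes:
        m = modules[node]
        kw = np.array([within[n] for n in module_members[m]], dtype=float)
        sd = kw.std(ddof=0)
        zi = (within[node] - kw.mean()) / sd if sd > 0 else 0.0
        k = g.degree(node)
        if k == 0:
            pi = 0.0
        else:
            pi = 1.0 - sum((c / k) ** 2 for c in per_module_links[node].values())
        if zi >= ZI_THRESHOLD:
            role = "network hub" if pi >= PI_THRESHOLD else "module hub"
        else:
            role = "connector" if pi >= PI_THRESHOLD else "peripheral"
        rows.append({"node": node, "module": m, "Zi": zi, "Pi": pi, "role": role})
    return pd.DataFrame(rows).set_index("node")


# ---------------------------------------------------------------------------
# Natural connectivity and robustness
# ---------------------------------------------------------------------------


def natural_connectivity(g: nx.Graph) -> float:
    """Natural connectivity lambda_bar = ln((1/N) sum_i exp(lambda_i)),
    the lambda_i being adjacency eigenvalues of the unweighted graph.

    Computed stably by shifting by the largest eigenvalue.  Non-negative
    for every graph (Jensen); 0 for an edgeless graph.  Returns NaN for
    the empty graph.
    """
    n = g.number_of_nodes()
    if n == 0:
        return float("nan")
    if g.number_of_edges() == 0:
        return 0.0
    a = nx.to_numpy_array(g, weight=None)
    evals = np.linalg.eigvalsh(a)
    lmax = evals[-1]
    return float(lmax + np.log(np.exp(evals - lmax).mean()))


@dataclass
class RobustnessCurve:
    points: pd.DataFrame  # columns: fraction, rep, lambda_bar
    slope: float
    intercept: float
    r_squared: float

    @property
    def fractions(self) -> np.ndarray:
        return np.unique(self.points["fraction"].to_numpy())


def robustness_curve(
    g: nx.Graph,
    fractions=tuple(np.round(np.arange(0.05, 0.51, 0.05), 2)),
    reps: int = 100,
    seed: int = 0,
) -> RobustnessCurve:
    """Natural connectivity after random node removal.

    For each fraction f and replicate, ceil(f*N) nodes are removed
    uniformly without replacement and lambda_bar recomputed on the induced
    subgraph (N in the formula is the post-removal node count).  The curve
    summary is the OLS fit of lambda_bar on f over all (f, rep) points.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValidationError("cannot assess robustness of an empty graph")
    fractions = [float(f) for f in fractions]
    if any(not 0 < f < 1 for f in fractions):
        raise ValidationError("removal fractions must lie strictly in (0, 1)")
    if max(int(np.ceil(f * n)) for f in fractions) >= n:
        raise ValidationError("a removal fraction would delete every node")
    if reps < 1:
        raise ValidationError("need at least one replicate")
    rng = np.random.default_rng(seed)
    nodes = list(g.nodes)
    records = []
    for f in fractions:
        k = int(np.ceil(f * n))
        for rep in range(reps):
            removed = set(rng.choice(n, size=k, replace=False).tolist())
            keep = [nodes[i] for i in range(n) if i not in removed]
            records.append(
                {"fraction": f, "rep": rep, "lambda_bar": natural_connectivity(g.subgraph(keep))}
            )
    points = pd.DataFrame(records)
    if len(set(fractions)) < 2:
        # slope needs at least two fraction levels; points still reported
        return RobustnessCurve(points, float("nan"), float("nan"), float("nan"))
    x = points["fraction"].to_numpy()
    y = points["lambda_bar"].to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - (resid**2).sum() / ss_tot
    return RobustnessCurve(points, float(slope), float(intercept), float(r2))


@dataclass
class SlopeComparison:
    delta_slope: float  # slope(b) - slope(a)
    t_statistic: float
    df: int
    p_value: float


def compare_robustness(a: RobustnessCurve, b: RobustnessCurve) -> SlopeComparison:
    """Test whether two robustness curves decline at different rates.

    Fits a two-line regression lambda_bar ~ fraction * group and t-tests
    the interaction (slope-difference) coefficient, two-sided.
    """
    for curve, name in ((a, "first"), (b, "second")):
        if curve.points["fraction"].nunique() < 2:
            raise ValidationError(f"slope not identifiable: {name} curve has a single fraction level")
    frames = []
    for gi, curve in enumerate((a, b)):
        f = curve.points.copy()
        f["grp"] = gi
        frames.append(f)
    data = pd.concat(frames, ignore_index=True)
    x = np.column_stack(
        [
            np.ones(len(data)),
            data["fraction"],
            data["grp"],
            data["fraction"] * data["grp"],
        ]
    )
    y = data["lambda_bar"].to_numpy()
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    df = len(y) - x.shape[1]
    if df <= 0:
        raise ValidationError("not enough points to test the slope difference")
    sigma2 = (resid**2).sum() / df
    cov = sigma2 * np.linalg.inv(x.T @ x)
    se = np.sqrt(cov[3, 3])
    t_stat = coef[3] / se if se > 0 else np.inf
    p = 2 * stats.t.sf(abs(t_stat), df=df)
    return SlopeComparison(float(coef[3]), float(t_stat), int(df), float(p))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def annotate_network(g: nx.Graph, zipi: pd.DataFrame) -> nx.Graph:
    """Attach module/Zi/Pi/role node attributes (in place) and return g."""
    for node, row in zipi.iterrows():
        if node in g.nodes:
            g.nodes[node].update(
                module=int(row["module"]), Zi=float(row["Zi"]),
                Pi=float(row["Pi"]), role=str(row["role"]),
            )
    return g


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def write_edge_list(g: nx.Graph, path) -> None:
    rows = [
        {"source": u, "target": v, "spearman_r": d.get("spearman_r"),
         "p": d.get("p"), "sign": d.get("sign")}
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "spearman_r", "p", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
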