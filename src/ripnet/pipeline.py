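"""End-to-end orchestration: run every analysis stage and write the
result bundle to an output directory.

Stage order: alpha diversity + group tests -> Bray-Curtis / PCoA /
PERMANOVA -> RDA / envfit / Mantel table -> per-group co-occurrence
networks with modules, Zi-Pi and robustness -> hydrological trends (if a
series file is supplied).  All randomness derives from the config seed via
named child seeds, so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import conet, diversity, env_linkage, hydro_trends
from .core_io import (
    AbundanceTable,
    EnvTable,
    PipelineConfig,
    RipnetError,
    filter_and_normalize,
    stage_seed,
)

logger = logging.getLogger("ripnet")

FLOAT_FORMAT = "%.10g"  # fixed-precision serialization => reproducible bytes


@dataclass
class GroupNetworkResult:
    group: str
    network: "object"  # nx.Graph
    metrics: conet.NetworkMetrics
    zipi: pd.DataFrame
    robustness: conet.RobustnessCurve


@dataclass
class ResultBundle:
    alpha: pd.DataFrame
    alpha_tests: pd.DataFrame
    distance: pd.DataFrame
    ordination: diversity.OrdinationResult
    permanova: diversity.PermanovaResult
    rda: env_linkage.RdaResult | None
    envfit: pd.DataFrame | None
    mantel: pd.DataFrame | None
    networks: dict[str, GroupNetworkResult]
    robustness_comparison: conet.SlopeComparison | None
    trends: pd.DataFrame | None
    config: PipelineConfig


class StageError(RipnetError):
    """Wraps a failure with the name of the stage that raised it."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except RipnetError as exc:
                raise StageError(f"stage {name!r}: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(
    table: AbundanceTable,
    env: EnvTable | None,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    series: dict[str, pd.DataFrame] | None = None,
    env_variables: list[str] | None = None,
) -> ResultBundle:
    """Run every stage on an in-memory dataset; optionally write all
    artifacts under ``out_dir``.  ``series`` maps a name (e.g. river) to a
    (time, value) DataFrame for the trend stage."""
    seed = config.seed
    logger.info("pipeline config: %s", config.to_dict())

    # --- diversity --------------------------------------------------------
    alpha = _stage("alpha_diversity")(diversity.alpha_diversity)(table)
    test_rows = []
    if len(table.group_names()) >= 2:
        for metric in ("richness", "shannon", "evenness"):
            vals = alpha[metric]
            ok = ~vals.isna()
            h, p = diversity.kruskal_wallis(vals[ok], alpha["group"][ok])
            test_rows.append({"metric": metric, "H": h, "p": p})
    alpha_tests = pd.DataFrame(test_rows)

    dist = _stage("bray_curtis")(diversity.bray_curtis)(table)
    ordination = _stage("pcoa")(diversity.pcoa)(dist)
    perma = _stage("permanova")(diversity.permanova)(
        dist, table.groups, n_perm=config.n_perm, seed=stage_seed(seed, "permanova")
    )

    # --- environment linkage ----------------------------------------------
    rda = fitted = mant = None
    if env is not None:
        env = env.align_to(table)
        variables = env_variables or env.variables
        rda = _stage("rda")(env_linkage.rda_fit)(
            table, env, variables, n_perm=config.n_perm, seed=stage_seed(seed, "rda")
        )
        fitted = _stage("envfit")(env_linkage.envfit)(
            ordination, env, variables, n_perm=config.n_perm, seed=stage_seed(seed, "envfit")
        )
        mant = _stage("mantel")(env_linkage.mantel_table)(
            dist, env, variables, n_perm=config.n_perm, seed=stage_seed(seed, "mantel")
        )

    # --- per-group networks ------------------------------------------------
    networks: dict[str, GroupNetworkResult] = {}
    for group in table.group_names():
        sub = table.subset_group(group)
        if sub.n_samples < 3:
            logger.warning("group %r has %d samples; network stage skipped",
                           group, sub.n_samples)
            continue
        try:
            norm = filter_and_normalize(sub, config.prevalence_min, scope="all")
            edges = conet.spearman_filtered(
                norm, r_min=config.r_min, alpha=config.alpha,
                correction=config.p_correction,
            )
            nodes = norm.taxon_ids if config.include_isolates else None
            g = conet.build_network(edges, taxonomy=table.taxonomy, nodes=nodes)
            modules, q = conet.detect_modules(g, seed=stage_seed(seed, f"louvain:{group}"))
            metrics = conet.network_metrics(g, modularity=q)
            zipi = (conet.zipi_roles(g, modules) if g.number_of_nodes()
                    else pd.DataFrame(columns=["module", "Zi", "Pi", "role"]))
            conet.annotate_network(g, zipi)
            if g.number_of_nodes() >= 4:
                rob = conet.robustness_curve(
                    g, fractions=config.removal_fractions, reps=config.removal_reps,
                    seed=stage_seed(seed, f"robustness:{group}"),
                )
            else:
                logger.warning("group %r network too small for robustness", group)
                rob = None
            networks[group] = GroupNetworkResult(group, g, metrics, zipi, rob)
        except RipnetError as exc:
            raise StageError(f"stage 'network:{group}': {exc}") from exc

    comparison = None
    curves = [r.robustness for r in networks.values() if r.robustness is not None]
    if len(curves) == 2:
        comparison = conet.compare_robustness(curves[0], curves[1])

    # --- hydrological trends ------------------------------------------------
    trends = None
    if series:
        rows = []
        for name, df in series.items():
            t = df.iloc[:, 0].to_numpy(dtype=float)
            y = df.iloc[:, 1].to_numpy(dtype=float)
            res = _stage(f"trend:{name}")(hydro_trends.trend_analysis)(t, y)
            summ = hydro_trends.coefficient_of_variation(y) if y.mean() > 0 else None
            rows.append({
                "series": name, "slope": res.slope, "intercept": res.intercept,
                "S": res.s, "Z": res.z, "p": res.p_value, "stars": res.stars,
                "cv": summ.cv if summ else np.nan, "n": res.n,
            })
        trends = pd.DataFrame(rows).set_index("series")

    bundle = ResultBundle(
        alpha=alpha, alpha_tests=alpha_tests, distance=dist, ordination=ordination,
        permanova=perma, rda=rda, envfit=fitted, mantel=mant, networks=networks,
        robustness_comparison=comparison, trends=trends, config=config,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: ResultBundle, out_dir: str | Path) -> None:
    """Serialize every stage output as TSV/GraphML/JSON under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ff = FLOAT_FORMAT

    with open(out / "config.txt", "w") as fh:
        for k, v in bundle.config.to_dict().items():
            fh.write(f"{k}: {v}\n")

    bundle.alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", float_format=ff)
    bundle.alpha_tests.to_csv(out / "alpha_tests.tsv", sep="\t", index=False, float_format=ff)
    bundle.distance.to_csv(out / "bray_curtis.tsv", sep="\t", float_format=ff)

    coords = bundle.ordination.coordinates.copy()
    with open(out / "pcoa_coordinates.tsv", "w") as fh:
        evals = "\t".join(FLOAT_FORMAT % v for v in bundle.ordination.eigenvalues)
        fh.write(f"# eigenvalues\t{evals}\n")
        coords.to_csv(fh, sep="\t", float_format=ff)

    pd.DataFrame([{
        "pseudo_F": bundle.permanova.pseudo_f, "R2": bundle.permanova.r_squared,
        "p": bundle.permanova.p_value, "n_perm": bundle.permanova.n_perm,
    }]).to_csv(out / "permanova.tsv", sep="\t", index=False, float_format=ff)

    if bundle.rda is not None:
        bundle.rda.site_scores.to_csv(out / "rda_sites.tsv", sep="\t", float_format=ff)
        bundle.rda.biplot_vectors.to_csv(out / "rda_biplot.tsv", sep="\t", float_format=ff)
        pd.DataFrame([{
            "total_explained": bundle.rda.total_explained,
            "pseudo_F": bundle.rda.pseudo_f, "p": bundle.rda.p_value,
            "n_perm": bundle.rda.n_perm,
        }]).to_csv(out / "rda_summary.tsv", sep="\t", index=False, float_format=ff)
    if bundle.envfit is not None:
        bundle.envfit.to_csv(out / "envfit.tsv", sep="\t", float_format=ff)
    if bundle.mantel is not None:
        bundle.mantel.to_csv(out / "mantel.tsv", sep="\t", float_format=ff)

    metric_rows = []
    for group, res in bundle.networks.items():
        conet.write_graphml(res.network, out / f"network_{group}.graphml")
        conet.write_edge_list(res.network, out / f"edges_{group}.tsv")
        res.zipi.to_csv(out / f"zipi_{group}.tsv", sep="\t", float_format=ff)
        metric_rows.append({"group": group, **res.metrics.to_dict()})
        if res.robustness is not None:
            res.robustness.points.to_csv(
                out / f"robustness_{group}.tsv", sep="\t", index=False, float_format=ff
            )
            with open(out / f"robustness_fit_{group}.txt", "w") as fh:
                fh.write(f"slope: {res.robustness.slope:.10g}\n")
                fh.write(f"intercept: {res.robustness.intercept:.10g}\n")
                fh.write(f"r_squared: {res.robustness.r_squared:.10g}\n")
    if metric_rows:
        pd.DataFrame(metric_rows).to_csv(
            out / "network_metrics.tsv", sep="\t", index=False, float_format=ff
        )
    if bundle.robustness_comparison is not None:
        c = bundle.robustness_comparison
        pd.DataFrame([{
            "delta_slope": c.delta_slope, "t": c.t_statistic, "df": c.df, "p": c.p_value,
        }]).to_csv(out / "robustness_comparison.tsv", sep="\t", index=False, float_format=ff)

    if bundle.trends is not None:
        bundle.trends.to_csv(out / "trends.tsv", sep="\t", float_format=ff)
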