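"""Typed data model, file readers/writers, filtering and normalization.

Conventions used throughout the package:

* abundance tables are stored taxa x samples (taxa are rows), matching
  the common OTU-table file dialect;
* counts are non-negative integers; relative abundances are floats whose
  columns sum to 1;
* every sample carries a group label (e.g. ``EastRiver`` / ``WestRiver``);
* all randomness flows from one master seed, from which per-stage child
  seeds are derived deterministically (see :func:`stage_seed`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ripnet")

TAXONOMY_COLUMN = "taxonomy"


class RipnetError(Exception):
    """Base class for all package errors."""


class ParseError(RipnetError):
    """Malformed input file; message names the offending row/column."""


class ValidationError(RipnetError):
    """An in-memory object violates its invariants."""


class EmptyResultError(RipnetError):
    """A filter or analysis step produced an empty result."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix with taxonomy and group labels.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon id with one numeric column per sample.
        Integer counts for raw tables; floats after normalization.
    taxonomy
        Per-taxon phylum label (``"Unclassified"`` allowed), aligned with
        ``counts.index``.
    groups
        Per-sample group label, aligned with ``counts.columns``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate taxon ids: {dups[:5]}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if (vals < 0).any():
            ti, si = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at ({self.counts.index[ti]}, {self.counts.columns[si]})"
            )
        self.taxonomy = self.taxonomy.reindex(self.counts.index)
        if self.taxonomy.isna().any():
            missing = self.taxonomy.index[self.taxonomy.isna()].tolist()
            raise ValidationError(f"taxa without taxonomy label: {missing[:5]}")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValidationError(f"samples without group label: {missing[:5]}")

    # -- basic accessors ----------------------------------------------------

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def group_names(self) -> list[str]:
        """Group labels in order of first appearance."""
        return list(dict.fromkeys(self.groups))

    def subset_group(self, group: str) -> "AbundanceTable":
        """Restrict to the samples of one group (taxa unchanged)."""
        keep = self.groups[self.groups == group].index
        if len(keep) == 0:
            raise ValidationError(f"no samples in group {group!r}")
        return AbundanceTable(
            counts=self.counts[keep], taxonomy=self.taxonomy, groups=self.groups[keep]
        )

    def equals(self, other: "AbundanceTable") -> bool:
        return (
            self.counts.equals(other.counts)
            and self.taxonomy.equals(other.taxonomy)
            and self.groups.equals(other.groups)
        )


@dataclass
class EnvTable:
    """Per-sample environmental variables (soil + hydrology), numeric.

    ``data`` is samples x variables.  Missing values are rejected when a
    variable is used, not at load time, so partially filled sheets load.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in environmental table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def select(self, variables: Sequence[str]) -> pd.DataFrame:
        """Return the named columns, erroring on unknown names or NaNs."""
        unknown = [v for v in variables if v not in self.data.columns]
        if unknown:
            raise ValidationError(f"unknown environmental variables: {unknown}")
        sub = self.data[list(variables)]
        if sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise ValidationError(f"missing values in environmental variables: {bad}")
        for v in variables:
            if sub[v].nunique() <= 2 and len(sub) > 2:
                logger.warning(
                    "environmental variable %r has <=2 distinct values "
                    "(river-level constant?); distance on it is two-valued", v
                )
        return sub

    def align_to(self, table: AbundanceTable) -> "EnvTable":
        missing = [s for s in table.sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"environmental table missing samples: {missing[:5]}")
        return EnvTable(self.data.loc[table.sample_ids])


@dataclass
class PipelineConfig:
    """Thresholds and permutation settings shared across pipeline stages.

    Defaults follow the edge rule |rho| >= 0.6 with p < 0.05 and
    999-permutation tests; the prevalence filter keeps taxa present in at
    least half the samples of a group before network construction.
    """

    r_min: float = 0.6
    alpha: float = 0.05
    n_perm: int = 999
    prevalence_min: float = 0.5
    removal_fractions: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.51, 0.05), 2))
    removal_reps: int = 100
    p_correction: str = "none"  # or "BH"
    include_isolates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r_min <= 1:
            raise ValidationError(f"r_min must be in (0, 1], got {self.r_min}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_perm < 99:
            raise ValidationError(f"n_perm must be >= 99, got {self.n_perm}")
        if not 0 <= self.prevalence_min <= 1:
            raise ValidationError("prevalence_min must be in [0, 1]")
        fr = tuple(float(f) for f in self.removal_fractions)
        if any(not 0 < f < 1 for f in fr):
            raise ValidationError("removal fractions must lie strictly in (0, 1)")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValidationError("removal fractions must be strictly increasing")
        self.removal_fractions = fr
        if self.removal_reps < 1:
            raise ValidationError("removal_reps must be >= 1")
        if self.p_correction not in ("none", "BH"):
            raise ValidationError("p_correction must be 'none' or 'BH'")

    def to_dict(self) -> dict:
        return {
            "r_min": self.r_min,
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "prevalence_min": self.prevalence_min,
            "removal_fractions": list(self.removal_fractions),
            "removal_reps": self.removal_reps,
            "p_correction": self.p_correction,
            "include_isolates": self.include_isolates,
            "seed": self.seed,
        }


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic child seed for a named stage, below 2**31."""
    child = np.random.SeedSequence([master_seed, abs(hash(stage)) % (2**31)])
    return int(child.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sep(fmt: str | None, path: Path) -> str:
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ParseError(f"unknown format {fmt!r}")
    return "\t" if fmt == "tsv" else ","


def read_abundance_table(
    path: str | Path,
    metadata_path: str | Path | None = None,
    fmt: str | None = None,
) -> AbundanceTable:
    """Read a taxa x samples count table (first column taxon id, one
    ``taxonomy`` column, remaining columns integer counts per sample).

    Group labels come from ``metadata_path`` (sample, group columns); if
    omitted, every sample is assigned group ``"all"``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep(fmt, path), index_col=0)
    if TAXONOMY_COLUMN not in df.columns:
        raise ParseError(f"missing {TAXONOMY_COLUMN!r} column in {path.name}")
    taxonomy = df[TAXONOMY_COLUMN].astype(str)
    counts = df.drop(columns=[TAXONOMY_COLUMN])
    for col in counts.columns:
        coerced = pd.to_numeric(counts[col], errors="coerce")
        if coerced.isna().any():
            row = counts.index[coerced.isna()][0]
            raise ParseError(f"non-numeric count at ({row}, {col})")
        counts[col] = coerced
    vals = counts.to_numpy()
    if (vals < 0).any():
        ti, si = np.argwhere(vals < 0)[0]
        raise ParseError(f"negative count at ({counts.index[ti]}, {counts.columns[si]})")
    if np.issubdtype(vals.dtype, np.floating) and np.allclose(vals, np.round(vals)):
        counts = counts.astype(np.int64)
    if metadata_path is not None:
        meta = read_metadata(metadata_path)
        groups = meta["group"].reindex(counts.columns)
        if groups.isna().any():
            missing = groups.index[groups.isna()].tolist()
            raise ParseError(f"metadata missing group for samples: {missing[:5]}")
    else:
        groups = pd.Series("all", index=counts.columns, name="group")
    try:
        return AbundanceTable(counts=counts, taxonomy=taxonomy, groups=groups)
    except ValidationError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc


def write_abundance_table(table: AbundanceTable, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    out = table.counts.copy()
    out.insert(0, TAXONOMY_COLUMN, table.taxonomy)
    out.index.name = "taxon_id"
    out.to_csv(path, sep=_sep(fmt, path))


def read_metadata(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read sample metadata: first column sample id, a ``group`` column,
    remaining numeric columns are environmental variables."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep(fmt, path), index_col=0)
    if "group" not in df.columns:
        raise ParseError(f"missing 'group' column in {path.name}")
    return df


def env_table_from_metadata(meta: pd.DataFrame) -> EnvTable:
    """Extract the numeric environmental columns from a metadata frame."""
    env = meta.drop(columns=["group"]).apply(pd.to_numeric, errors="coerce")
    return EnvTable(env)


def read_env_table(path: str | Path, fmt: str | None = None) -> EnvTable:
    return env_table_from_metadata(read_metadata(path, fmt))


def read_series(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a two-column (time, value) series file; extra columns are kept
    so multi-site files can be split by the caller."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep(fmt, path))
    if df.shape[1] < 2:
        raise ParseError(f"{path.name}: need at least (time, value) columns")
    for col in df.columns[:2]:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ParseError(f"{path.name}: column {col!r} is not numeric")
    return df


# ---------------------------------------------------------------------------
# Filtering / normalization
# ---------------------------------------------------------------------------


def filter_by_prevalence(
    table: AbundanceTable, prevalence_min: float, scope: str = "all"
) -> AbundanceTable:
    """Keep taxa present (count > 0) in at least ``prevalence_min`` of
    samples.  ``scope='group'`` applies the threshold within every group
    and keeps taxa that pass in at least one group."""
    if not 0 <= prevalence_min <= 1:
        raise ValidationError("prevalence_min must be in [0, 1]")
    present = table.counts.to_numpy() > 0
    if scope == "all":
        keep = present.mean(axis=1) >= prevalence_min
    elif scope == "group":
        keep = np.zeros(table.n_taxa, dtype=bool)
        for g in table.group_names():
            cols = np.asarray(table.groups == g)
            keep |= present[:, cols].mean(axis=1) >= prevalence_min
    else:
        raise ValidationError(f"unknown scope {scope!r}")
    if not keep.any():
        raise EmptyResultError(
            f"prevalence filter at {prevalence_min} removed every taxon"
        )
    return AbundanceTable(
        counts=table.counts.loc[keep],
        taxonomy=table.taxonomy,
        groups=table.groups,
    )


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Rescale each sample column to sum to 1."""
    totals = table.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"cannot normalize zero-sum samples: {zero}")
    rel = table.counts / totals
    return AbundanceTable(counts=rel, taxonomy=table.taxonomy, groups=table.groups)


def filter_and_normalize(
    table: AbundanceTable, prevalence_min: float, scope: str = "all"
) -> AbundanceTable:
    """Prevalence filter followed by per-sample relative-abundance scaling."""
    return to_relative_abundance(filter_by_prevalence(table, prevalence_min, scope))
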