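"""Cross-domain gene-flow quantification from per-gene closest-taxon tables.

The input table mirrors an orthology-mapper export: one row per gene with
its genome, nucleotide length, closest-taxon group (Archaea / Bacteria /
Eukaryota / Unassigned) and optional one-letter COG category.  The analyses:

* per-genome counts by group and scaling fits of each group's count against
  the total gene count G (ordinary least squares, closed form) - the archaeal
  intercept is the "extrapolated base number" of archaeal genes;
* the archaea:bacteria gene-count ratio as a function of genome size;
* COG-category profiles per taxon group (unknown-function genes excluded);
* taxon-group percentages of total gene length for mobile-element gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TAXON_GROUPS = ("Archaea", "Bacteria", "Eukaryota", "Unassigned")
UNKNOWN_FUNCTION_COGS = {"S"}  # plus missing/NaN

REQUIRED_COLUMNS = ("genome_id", "gene_id", "gene_length_nt", "taxon_group")


def validate_gene_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"gene table missing column {col!r}")
    bad = set(table["taxon_group"]) - set(TAXON_GROUPS)
    if bad:
        raise ValueError(f"unknown taxon groups: {sorted(bad)}")
    if (table["gene_length_nt"] <= 0).any():
        raise ValueError("gene lengths must be positive")
    dup = table.duplicated(subset=["genome_id", "gene_id"])
    if dup.any():
        raise ValueError("duplicate gene ids within a genome")
    return table


def count_by_group(table: pd.DataFrame) -> pd.DataFrame:
    """Per-genome gene counts per taxon group plus the total G (a partition)."""
    validate_gene_table(table)
    counts = (
        table.groupby(["genome_id", "taxon_group"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(TAXON_GROUPS), fill_value=0)
    )
    counts.columns.name = None
    counts["G"] = counts[list(TAXON_GROUPS)].sum(axis=1)
    return counts.reset_index()


@dataclass
class GroupFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r2: float
    n: int

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        t = stats.t.ppf(0.5 + level / 2, self.n - 2)
        return (self.slope - t * self.slope_se, self.slope + t * self.slope_se)


@dataclass
class ScalingFit:
    groups: dict[str, GroupFit]

    @property
    def archaeal_base(self) -> float:
        """Extrapolated base number of archaeal genes (the archaeal intercept)."""
        return self.groups["Archaea"].intercept


def _ols(x: np.ndarray, y: np.ndarray) -> GroupFit:
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    # closed-form normal equations
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    dof = n - 2
    sigma2 = sse / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(xtx)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return GroupFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        slope_se=float(np.sqrt(cov[1, 1])),
        intercept_se=float(np.sqrt(cov[0, 0])),
        r2=r2,
        n=n,
    )


def fit_scaling(counts: pd.DataFrame) -> ScalingFit:
    """OLS of each group's gene count against the total gene count G."""
    if len(counts) < 3:
        raise ValueError("need counts for at least 3 genomes")
    G = counts["G"].to_numpy(dtype=float)
    if np.all(G == G[0]):
        raise ValueError("total gene counts are all equal; degenerate design")
    fits = {
        g: _ols(G, counts[g].to_numpy(dtype=float)) for g in TAXON_GROUPS
    }
    return ScalingFit(groups=fits)


def ratio_vs_size(
    counts: pd.DataFrame, genome_sizes_bp: dict[str, int]
) -> pd.DataFrame:
    """Archaea:Bacteria count ratio per genome, sorted by genome size."""
    rows = []
    for _, row in counts.iterrows():
        gid = row["genome_id"]
        if gid not in genome_sizes_bp:
            raise ValueError(f"no genome size for {gid!r}")
        bact = row["Bacteria"]
        rows.append(
            {
                "genome_id": gid,
                "genome_size_bp": genome_sizes_bp[gid],
                "archaea": row["Archaea"],
                "bacteria": bact,
                "ratio": row["Archaea"] / bact if bact > 0 else np.nan,
                "undefined": bact == 0,
            }
        )
    return pd.DataFrame(rows).sort_values("genome_size_bp").reset_index(drop=True)


def cog_taxon_profile(table: pd.DataFrame) -> pd.DataFrame:
    """Fraction of genes per COG category within each taxon group.

    Unknown-function genes (category S or no category) are excluded;
    fractions sum to 1 within each group that has any informative gene.
    """
    validate_gene_table(table)
    if "cog_category" not in table.columns:
        raise ValueError("gene table has no cog_category column")
    t = table.dropna(subset=["cog_category"])
    t = t[~t["cog_category"].isin(UNKNOWN_FUNCTION_COGS) & (t["cog_category"] != "")]
    if t.empty:
        import logging

        logging.getLogger("mobilome").warning(
            "all genes are unknown-function; empty COG profile"
        )
        return pd.DataFrame(columns=["taxon_group", "cog_category", "fraction"])
    prof = (
        t.groupby(["taxon_group", "cog_category"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    prof["fraction"] = prof.groupby("taxon_group")["n"].transform(lambda s: s / s.sum())
    return prof[["taxon_group", "cog_category", "fraction", "n"]]


def enriched_categories(profile: pd.DataFrame, top: int = 3) -> dict[str, list[str]]:
    """Per group: categories with the largest fraction excess over other groups."""
    wide = profile.pivot_table(
        index="cog_category", columns="taxon_group", values="fraction", fill_value=0.0
    )
    out: dict[str, list[str]] = {}
    for group in wide.columns:
        others = wide.drop(columns=[group])
        excess = wide[group] - (others.max(axis=1) if len(others.columns) else 0.0)
        ranked = excess[excess > 0].sort_values(ascending=False)
        out[group] = list(ranked.index[:top])
    return out


def mge_length_fractions(table: pd.DataFrame) -> pd.Series:
    """Percentage of the total gene length attributed to each taxon group."""
    validate_gene_table(table)
    if table.empty:
        raise ValueError("empty gene table")
    total = table["gene_length_nt"].sum()
    frac = (
        table.groupby("taxon_group")["gene_length_nt"].sum() / total * 100.0
    ).reindex(list(TAXON_GROUPS), fill_value=0.0)
    frac.name = "percent_of_gene_length"
    return frac
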