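"""Expression binning and methylation/density-expression correlations.

Expression is consumed as a precomputed per-gene FPKM table. Genes above
100 FPKM (a small tail) are flagged and excluded from methylation
correlations; regions enter correlations only with a minimum number of
covered CpG sites (2, or 4 for CpG islands, which RRBS covers densely).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, UndefinedResultError

DEFAULT_EDGES = (0.0, 0.1, 1.0, 10.0, 100.0)


def bin_expression(records: pd.DataFrame, edges=DEFAULT_EDGES,
                   exclude_top: bool = True) -> pd.DataFrame:
    """Assign ordered expression bins to an FPKM table.

    Bin 0 is "no expression" (fpkm < edges[1]); successive bins are
    half-open, except that the top retained edge is right-inclusive
    (fpkm == edges[-1] stays in the last bin). With ``exclude_top``,
    fpkm above the last edge is flagged ``excluded`` and given no bin.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ParameterError("bin edges must be strictly increasing")
    fpkm = records["fpkm"].to_numpy(float)
    if (fpkm < 0).any():
        raise ParameterError("fpkm must be non-negative")
    out = records.copy()
    bins = np.searchsorted(edges[1:], fpkm, side="right")
    top = len(edges) - 2
    bins[fpkm == edges[-1]] = top  # right-inclusive last retained bin
    excluded = np.zeros(fpkm.size, bool)
    if exclude_top:
        excluded = fpkm > edges[-1]
    bins = bins.astype(float)
    bins[excluded] = np.nan
    out["bin"] = bins
    out["excluded"] = excluded
    return out


def spearman(x, y) -> dict:
    """Spearman rank correlation with average ranks.

    rho is the Pearson correlation of the rank vectors; the p-value uses
    the large-sample t approximation t = rho*sqrt((n-2)/(1-rho^2)) with
    n-2 degrees of freedom (p = 0 at |rho| = 1).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 observations")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedResultError("zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return {"rho": rho, "p": p, "n": n}


MIN_SITES = {"CGI": 4}
DEFAULT_MIN_SITES = 2


def _min_sites(region_kind: str) -> int:
    return MIN_SITES.get(region_kind, DEFAULT_MIN_SITES)


def correlate_meth_expr(stats_table: pd.DataFrame, expression: pd.DataFrame,
                        region_kind: str, tissue: str | None = None,
                        min_genes: int = 30) -> dict:
    """Spearman correlation between per-gene region methylation and FPKM.

    ``stats_table`` carries one row per gene/region kind with
    ``n_cpg_sites`` and ``mean_level``; genes in the excluded expression
    bin (> 100 FPKM) and regions below the minimum-site rule are dropped.
    """
    sub = stats_table[stats_table["region"] == region_kind]
    sub = sub[sub["n_cpg_sites"] >= _min_sites(region_kind)]
    expr = expression if tissue is None else expression[expression["tissue"] == tissue]
    expr = bin_expression(expr)
    expr = expr[~expr["excluded"]]
    merged = sub.merge(expr[["gene", "fpkm"]], on="gene")
    if len(merged) < min_genes:
        raise UndefinedResultError(
            f"only {len(merged)} genes after filtering (< {min_genes})")
    return spearman(merged["mean_level"], merged["fpkm"])


def correlate_density_expr(densities: pd.DataFrame, expression: pd.DataFrame,
                           dinuc: str, tissue: str | None = None,
                           min_genes: int = 30) -> dict:
    """Spearman correlation between per-gene TSS-window dinucleotide
    density and FPKM."""
    sub = densities[densities["dinuc"] == dinuc]
    expr = expression if tissue is None else expression[expression["tissue"] == tissue]
    expr = bin_expression(expr)
    expr = expr[~expr["excluded"]]
    merged = sub.merge(expr[["gene", "fpkm"]], on="gene")
    if len(merged) < min_genes:
        raise UndefinedResultError(
            f"only {len(merged)} genes after filtering (< {min_genes})")
    return spearman(merged["density"], merged["fpkm"])


def correlate_per_tissue(fn, expression: pd.DataFrame, *args, **kwargs) -> pd.DataFrame:
    """Run a correlation per tissue and report the range across tissues,
    mirroring how ranges like "rho -0.20 to -0.25" are presented."""
    rows = []
    for tissue in sorted(expression["tissue"].unique()):
        res = fn(*args, expression=expression, tissue=tissue, **kwargs)
        rows.append({"tissue": tissue, **res})
    return pd.DataFrame(rows)
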