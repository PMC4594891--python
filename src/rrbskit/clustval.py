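"""Hierarchical clustering of tissues with bootstrap support, and the
cross-individual validation of top methylation/expression changes.

Tissues are clustered on their shared-site methylation profiles with the
Ward.D2 criterion (squared Euclidean distances inside the Lance-Williams
update; R's ``ward.D2`` equals scipy's ``ward`` on Euclidean distances).
Bootstrap support for an internal edge is the fraction of site-resampled
replicates whose dendrogram contains the same tissue cluster.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ParameterError
from .exprcorr import spearman


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    def clusters(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes, smallest first."""
        n = len(self.labels)
        members: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)}
        out = []
        for k, (a, b, _, _) in enumerate(self.linkage):
            members[n + k] = members[int(a)] | members[int(b)]
            out.append(members[n + k])
        return out

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def newick(self) -> str:
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: lab for i, lab in enumerate(self.labels)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[n + k] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            height[n + k] = h
        return node[n + len(self.linkage) - 1] + ";"


def _check_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if matrix.isna().any().any():
        raise ParameterError(
            "matrix contains missing values; clustering consumes shared "
            "(fully covered) sites only")
    if matrix.shape[1] < 3:
        raise ParameterError("need at least 3 columns to cluster")
    return matrix


def ward_cluster(matrix: pd.DataFrame) -> Dendrogram:
    """Agglomerative Ward.D2 clustering of the matrix columns."""
    m = _check_matrix(matrix)
    Z = hierarchy.linkage(m.to_numpy(float).T, method="ward")
    return Dendrogram(Z, list(m.columns))


def _weighted_linkage(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Ward linkage of columns under row weights (= row-resampling counts).

    Resampling rows with replacement is equivalent to multinomial row
    weights in the Gram matrix, so pairwise squared Euclidean distances of
    the resampled matrix come from G = X' diag(w) X without materialising
    the replicate.
    """
    G = (X * w[:, None]).T @ X
    d2 = np.add.outer(np.diag(G), np.diag(G)) - 2 * G
    np.fill_diagonal(d2, 0.0)
    cond = squareform(np.sqrt(np.maximum(d2, 0.0)), checks=False)
    return hierarchy.linkage(cond, method="ward")


def bootstrap_support(matrix: pd.DataFrame, n_boot: int = 10_000,
                      seed: int | None = None) -> pd.DataFrame:
    """Bootstrap probability of each internal cluster of the full-data tree.

    Rows (sites) are resampled with replacement ``n_boot`` times; support
    for a cluster is the percentage of replicates whose Ward.D2 tree
    contains it. Deterministic under ``seed``.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot = {n_boot} is small; supports will be noisy")
    m = _check_matrix(matrix)
    X = m.to_numpy(float)
    labels = list(m.columns)
    base = ward_cluster(m)
    targets = base.clusters()[:-1]  # root trivially always present
    hits = np.zeros(len(targets), np.int64)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    for _ in range(n_boot):
        w = rng.multinomial(n, np.full(n, 1.0 / n)).astype(float)
        Z = _weighted_linkage(X, w)
        found = set(Dendrogram(Z, labels).clusters())
        for i, t in enumerate(targets):
            if t in found:
                hits[i] += 1
    return pd.DataFrame({
        "cluster": [tuple(sorted(t)) for t in targets],
        "size": [len(t) for t in targets],
        "support_pct": 100.0 * hits / n_boot,
    })


def _log2_change(a: np.ndarray, b: np.ndarray, cap: float) -> np.ndarray:
    """log2(b/a) with +/-cap substituted for the infinite cases."""
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(b / a)
    fc[(a == 0) & (b > 0)] = cap
    fc[(b == 0) & (a > 0)] = -cap
    fc[(a == 0) & (b == 0)] = 0.0  # "no change" when both sides are zero
    return np.clip(fc, -cap, cap)


def top_changes(values_a: pd.Series, values_b: pd.Series, n: int = 10,
                cap: float = 6.0) -> pd.DataFrame:
    """The ``n`` sites with the largest increase and the ``n`` with the
    largest decrease of the value from a to b.

    Ranking is by the signed difference b - a (the "largest change in
    level"); each record also carries log2(b/a) with +/-cap substituted
    for the infinite cases, which downstream validation correlates. Keys
    with both values zero are excluded (no defined change); ties are
    broken by key order.
    """
    common = values_a.index.intersection(values_b.index)
    a = values_a.loc[common].to_numpy(float)
    b = values_b.loc[common].to_numpy(float)
    eligible = ~((a == 0) & (b == 0))
    fc = _log2_change(a[eligible], b[eligible], cap)
    df = pd.DataFrame({"key": np.asarray(common)[eligible],
                       "value_a": a[eligible], "value_b": b[eligible],
                       "difference": b[eligible] - a[eligible],
                       "log2_change": fc})
    df = df.sort_values(["difference", "key"],
                        ascending=[False, True], kind="stable")
    if len(df) < 2 * n:
        warnings.warn(f"only {len(df)} eligible keys (< {2 * n}); returning all")
        return df.reset_index(drop=True)
    out = pd.concat([df.head(n), df.tail(n)])
    return out.reset_index(drop=True)


def directional_agreement(main: pd.DataFrame, validation_a: pd.Series,
                          validation_b: pd.Series, cap: float = 6.0) -> dict:
    """Reproduce top changes in an independent dataset.

    Recomputes the capped log2 changes at the main set's keys from the
    validation values, counts sign agreement (a zero validation change
    counts as disagreement) and correlates the two change vectors.
    """
    keys = main["key"]
    avail = [k in validation_a.index and k in validation_b.index for k in keys]
    missing = int(len(keys) - sum(avail))
    if missing:
        warnings.warn(f"{missing} keys missing from validation dataset; excluded")
    sub = main[np.asarray(avail)]
    va = validation_a.loc[sub["key"]].to_numpy(float)
    vb = validation_b.loc[sub["key"]].to_numpy(float)
    val_fc = _log2_change(va, vb, cap)
    main_fc = sub["log2_change"].to_numpy(float)
    same = int(((np.sign(val_fc) == np.sign(main_fc)) & (val_fc != 0)).sum())
    corr = spearman(main_fc, val_fc)
    return {"n_same_direction": same, "n_total": len(sub),
            "n_missing": missing, "rho": corr["rho"], "p": corr["p"]}
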