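"""Allele-specific expression (ASE) calling.

Per-SNP allelic RNA read counts at confirmed heterozygous sites are
tested against a 50:50 allele ratio with an exact binomial test; p-values
are Benjamini-Hochberg corrected, and a gene is called ASE only when every
one of its retained SNPs is significant (q < 0.05). Mono-allelic genes
additionally show zero RNA reads on one consistent allele side.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

COUNT_COLS = ["gene", "chrom", "pos", "ref", "alt",
              "rna_ref", "rna_alt", "dna_ref", "dna_alt"]


def filter_ase_sites(counts: pd.DataFrame,
                     snp_positions: pd.DataFrame | None = None,
                     indel_positions: pd.DataFrame | None = None,
                     min_rna_depth: int = 10,
                     snp_distance: int = 20,
                     indel_distance: int = 15,
                     min_dna_ratio: float = 0.3,
                     dna_ratio_on: str = "dna") -> pd.DataFrame:
    """SNP-level ASE filters.

    Removes sites with RNA depth below ``min_rna_depth``; pairs of SNPs
    within ``snp_distance`` bp of each other (both removed); sites within
    ``indel_distance`` bp of an indel; and sites whose heterozygote allelic
    balance min/max falls below ``min_dna_ratio``. The balance is taken on
    DNA counts by default — applying it to RNA would delete true ASE —
    but ``dna_ratio_on="rna"`` switches to the RNA-level reading.
    """
    df = counts.reset_index(drop=True).copy()
    reasons = pd.Series("", index=df.index)

    rna_depth = df["rna_ref"] + df["rna_alt"]
    reasons[rna_depth < min_rna_depth] += "low_rna_depth;"

    if snp_positions is None:
        snp_positions = df[["chrom", "pos"]]
    near_snp = np.zeros(len(df), bool)
    for chrom, idx in df.groupby("chrom").indices.items():
        all_pos = np.sort(np.unique(
            snp_positions.loc[snp_positions["chrom"] == chrom, "pos"]
            .to_numpy(np.int64)))
        pos = df["pos"].to_numpy(np.int64)[idx]
        for k, p in enumerate(pos):
            i0, i1 = np.searchsorted(all_pos, [p - snp_distance,
                                               p + snp_distance + 1])
            others = all_pos[i0:i1]
            if (others != p).any():
                near_snp[idx[k]] = True
    reasons[near_snp] += "snp_within_20bp;"

    if indel_positions is not None and len(indel_positions):
        near_indel = np.zeros(len(df), bool)
        for chrom, idx in df.groupby("chrom").indices.items():
            ipos = np.sort(indel_positions.loc[
                indel_positions["chrom"] == chrom, "pos"].to_numpy(np.int64))
            if ipos.size == 0:
                continue
            pos = df["pos"].to_numpy(np.int64)[idx]
            i = np.searchsorted(ipos, pos)
            left = np.where(i > 0, pos - ipos[np.maximum(i - 1, 0)], np.iinfo(np.int64).max)
            right = np.where(i < ipos.size, ipos[np.minimum(i, ipos.size - 1)] - pos,
                             np.iinfo(np.int64).max)
            near_indel[idx] = np.minimum(left, right) <= indel_distance
        reasons[near_indel] += "indel_within_15bp;"

    c1, c2 = (("dna_ref", "dna_alt") if dna_ratio_on == "dna"
              else ("rna_ref", "rna_alt"))
    lo = np.minimum(df[c1], df[c2]).to_numpy(float)
    hi = np.maximum(df[c1], df[c2]).to_numpy(float)
    ratio = np.divide(lo, hi, out=np.zeros_like(lo), where=hi > 0)
    reasons[ratio < min_dna_ratio] += "allelic_balance;"

    df["removed_reason"] = reasons
    return df[reasons == ""].drop(columns="removed_reason").reset_index(drop=True)


def binomial_ase_test(rna_ref: int, rna_alt: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value for allelic imbalance.

    Two-sided in the minimum-likelihood sense: the sum of probabilities of
    all outcomes no more likely than the observed one.
    """
    if not 0 < p0 < 1:
        raise ParameterError("p0 must be in (0, 1)")
    n = rna_ref + rna_alt
    if n == 0:
        raise ParameterError("no reads")
    return float(stats.binomtest(rna_ref, n, p0).pvalue)


def bh_correct(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def evaluate_snps(counts: pd.DataFrame, p0: float = 0.5) -> pd.DataFrame:
    """Per-SNP binomial tests plus BH correction over all retained SNPs."""
    df = counts.reset_index(drop=True).copy()
    df["p"] = [binomial_ase_test(r, a, p0)
               for r, a in zip(df["rna_ref"], df["rna_alt"])]
    df["q"] = bh_correct(df["p"].to_numpy())
    return df


def call_gene_ase(snp_results: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Gene-level ASE calls from per-SNP results.

    A gene is ``ase`` iff *all* of its retained SNPs have q below the
    threshold, and ``monoallelic`` iff additionally every SNP has zero RNA
    reads on one consistent allele side (majority side when unphased).
    Genes with zero retained SNPs never appear (not tested).
    """
    if "tissue" not in snp_results:
        snp_results = snp_results.assign(tissue="all")
    rows = []
    for (gene, tissue), grp in snp_results.groupby(["gene", "tissue"]):
        n = len(grp)
        n_sig = int((grp["q"] < q_threshold).sum())
        call = "none"
        if n >= 1 and n_sig == n:
            call = "ase"
            sides = []
            for r, a in zip(grp["rna_ref"], grp["rna_alt"]):
                if a == 0 and r > 0:
                    sides.append("ref")
                elif r == 0 and a > 0:
                    sides.append("alt")
                else:
                    sides.append(None)
            if all(s is not None for s in sides):
                majority = max(set(sides), key=sides.count)
                if all(s == majority for s in sides):
                    call = "monoallelic"
                else:
                    warnings.warn(
                        f"gene {gene}: zero-sides inconsistent across SNPs; "
                        "not mono-allelic under the same-side rule")
        rows.append({"gene": gene, "tissue": tissue, "n_snps_tested": n,
                     "n_snps_ase": n_sig, "call": call})
    return pd.DataFrame(rows)


def tissue_specificity(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue ASE / mono-allelic tallies with unique-to-tissue counts.

    ``monoallelic`` calls count as ASE as well (mono-allelic expression is
    the extreme of allelic imbalance).
    """
    df = calls.copy()
    df["is_ase"] = df["call"].isin(["ase", "monoallelic"])
    df["is_mono"] = df["call"] == "monoallelic"
    ase_tissues = df[df["is_ase"]].groupby("gene")["tissue"].nunique()
    mono_tissues = df[df["is_mono"]].groupby("gene")["tissue"].nunique()
    rows = []
    for tissue, grp in df.groupby("tissue"):
        ase_genes = grp.loc[grp["is_ase"], "gene"]
        mono_genes = grp.loc[grp["is_mono"], "gene"]
        rows.append({
            "tissue": tissue,
            "n_ase": len(ase_genes),
            "n_unique_ase": int((ase_tissues[ase_genes] == 1).sum()),
            "n_monoallelic": len(mono_genes),
            "n_unique_monoallelic": int((mono_tissues[mono_genes] == 1).sum()),
        })
    return pd.DataFrame(rows)
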