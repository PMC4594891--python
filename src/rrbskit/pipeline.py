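"""End-to-end analysis over a simulated (or file-loaded) dataset.

Runs the stages in the order the protocol prescribes: reduced-genome
construction, bisulfite alignment, methylation calling, strand
combination, the minimum-depth site filter, conversion-rate estimation,
variant calling on both SNP-evidence datasets, SNP-aware CpG/non-CpG site
exclusion, and assembly of the shared-site methylation matrix used for
clustering and cross-individual validation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bscall, snpfilter
from .rrbs_reduce import build_reduced_genome
from .synthgenome import SimulatedData


@dataclass
class AnalysisResult:
    """All per-stage outputs of one pipeline run."""

    per_strand: dict[str, pd.DataFrame]
    combined: dict[str, pd.DataFrame]
    conversion_rate: float
    cpg_filter: bscall.SiteFilterResult
    noncpg_filter: bscall.SiteFilterResult
    control_variants: pd.DataFrame
    wgs_variants: pd.DataFrame
    control_window: tuple[int, int]
    wgs_window: tuple[int, int]
    cpg_validation: snpfilter.CpgValidation
    noncpg_excluded: pd.DataFrame
    shared_cpg: pd.DataFrame          # post SNP exclusion
    shared_noncpg: pd.DataFrame       # post SNP exclusion
    meth_matrix: pd.DataFrame         # shared CpG levels, sites x tissues
    noncpg_levels: dict[str, pd.DataFrame]
    alignment_stats: pd.DataFrame = field(default_factory=pd.DataFrame)


def _levels_at(table: pd.DataFrame, sites: pd.DataFrame,
               keys: list[str]) -> pd.DataFrame:
    return sites.merge(table, on=keys, how="left")


def run_analysis(sim: SimulatedData, min_depth: int = 10,
                 seed_len: int = 20, seed_mm: int = 1, read_mm: int = 2,
                 min_mapq: float = 20.0) -> AnalysisResult:
    """Run the full methylation pipeline on one simulated individual."""
    config = sim.config
    reduced = build_reduced_genome(sim.genome, *config.reduced_genome_range)
    aligner = bscall.BsAligner(reduced, seed_len=seed_len,
                               seed_mm=seed_mm, read_mm=read_mm)

    per_strand: dict[str, pd.DataFrame] = {}
    combined: dict[str, pd.DataFrame] = {}
    stats_rows = []
    for tissue, tissue_reads in sim.reads.items():
        alignments = []
        n_unmapped = n_ambiguous = 0
        for rid, seq in tissue_reads:
            res = aligner.align(rid, seq)
            if res.status == bscall.ALIGNED:
                alignments.append(res.alignment)
            elif res.status == bscall.AMBIGUOUS:
                n_ambiguous += 1
            else:
                n_unmapped += 1
        table = bscall.call_methylation(alignments, reduced,
                                        sim.genome.chromosomes)
        per_strand[tissue] = table
        combined[tissue] = bscall.combine_cpg_strands(table)
        stats_rows.append({"tissue": tissue, "n_reads": len(tissue_reads),
                           "n_aligned": len(alignments),
                           "n_unmapped": n_unmapped,
                           "n_ambiguous": n_ambiguous})
    alignment_stats = pd.DataFrame(stats_rows)

    pooled = pd.concat(per_strand.values(), ignore_index=True)
    conversion = bscall.estimate_conversion_rate(pooled)

    cpg_tables = {t: df[df["context"] == "CpG"] for t, df in combined.items()}
    noncpg_tables = {t: df[df["context"] != "CpG"] for t, df in combined.items()}
    cpg_filter = bscall.filter_sites(cpg_tables, min_depth)
    noncpg_filter = bscall.filter_sites(noncpg_tables, min_depth)

    # --- SNP evidence
    control_calls = snpfilter.call_variants(sim.control_pileups,
                                            sim.genome.chromosomes)
    wgs_calls = snpfilter.call_variants(sim.wgs_pileups, sim.genome.chromosomes)
    control_window = snpfilter.depth_window(sim.control_pileups.mean_coverage())
    wgs_window = snpfilter.depth_window(sim.wgs_pileups.mean_coverage())
    control_pass = snpfilter.filter_variants(control_calls, control_window, min_mapq)
    wgs_pass = snpfilter.filter_variants(wgs_calls, wgs_window, min_mapq)

    high_cpg = cpg_filter.high_confidence.to_frame(index=False)
    validation = snpfilter.validate_cpg_sites(
        high_cpg[["chrom", "pos"]],
        snpfilter.DatasetEvidence(sim.control_pileups, control_pass, control_window),
        snpfilter.DatasetEvidence(sim.wgs_pileups, wgs_pass, wgs_window))

    shared_cpg = cpg_filter.shared.to_frame(index=False)
    excl = validation.excluded
    shared_cpg = shared_cpg.merge(excl.assign(_snp=True), on=["chrom", "pos"],
                                  how="left")
    shared_cpg = shared_cpg[shared_cpg["_snp"].isna()].drop(columns="_snp")
    shared_cpg = shared_cpg.reset_index(drop=True)

    shared_noncpg = noncpg_filter.shared.to_frame(index=False)
    all_pass = pd.concat([control_pass, wgs_pass], ignore_index=True)
    noncpg_excl = snpfilter.validate_noncpg_sites(
        shared_noncpg[["chrom", "pos", "strand"]], all_pass)
    if len(noncpg_excl):
        shared_noncpg = shared_noncpg.merge(
            noncpg_excl.assign(_snp=True), on=["chrom", "pos", "strand"],
            how="left")
        shared_noncpg = (shared_noncpg[shared_noncpg["_snp"].isna()]
                         .drop(columns="_snp").reset_index(drop=True))

    # --- shared-site methylation matrix (sites x tissues)
    key = ["chrom", "pos"]
    mat = shared_cpg[key].copy()
    for tissue, df in cpg_tables.items():
        mat = mat.merge(df[key + ["level"]].rename(columns={"level": tissue}),
                        on=key, how="left")
    mat = mat.set_index(pd.MultiIndex.from_frame(mat[key]))[list(sim.reads)]

    noncpg_levels = {
        t: shared_noncpg[["chrom", "pos", "strand", "context"]].merge(
            df, on=["chrom", "pos", "strand", "context"], how="left")
        for t, df in noncpg_tables.items()}

    return AnalysisResult(
        per_strand=per_strand, combined=combined, conversion_rate=conversion,
        cpg_filter=cpg_filter, noncpg_filter=noncpg_filter,
        control_variants=control_pass, wgs_variants=wgs_pass,
        control_window=control_window, wgs_window=wgs_window,
        cpg_validation=validation, noncpg_excluded=noncpg_excl,
        shared_cpg=shared_cpg, shared_noncpg=shared_noncpg,
        meth_matrix=mat, noncpg_levels=noncpg_levels,
        alignment_stats=alignment_stats)


def shared_levels_frame(result: AnalysisResult, context: str = "CpG") -> pd.DataFrame:
    """Long-format shared-site levels (chrom, pos, tissue, level)."""
    if context == "CpG":
        df = result.meth_matrix.stack().rename("level").reset_index()
        df.columns = ["chrom", "pos", "tissue", "level"]
        return df
    rows = []
    for tissue, df in result.noncpg_levels.items():
        sub = df[df["context"] == context][["chrom", "pos", "strand", "level"]]
        rows.append(sub.assign(tissue=tissue))
    return pd.concat(rows, ignore_index=True)
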