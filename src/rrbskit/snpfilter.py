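"""Diploid genotyping from pileups and SNP-aware exclusion of methylation sites.

CpG dinucleotides mutate at a high rate (deamination of 5-methylcytosine),
and a C->T SNP at an interrogated cytosine is indistinguishable from an
unmethylated read. Sites carrying SNPs in either the targeted-control or
the WGS evidence are therefore excluded from methylation tables, after the
depth-window and mapping-quality filters.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

import numpy as np
import pandas as pd

from . import _seqtools as st
from .errors import ParameterError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

HOM_REF, HET, HOM_ALT = "hom_ref", "het", "hom_alt"


@dataclass
class ChromPileup:
    """Dense per-position pileup evidence for one chromosome."""

    counts: np.ndarray  # (4, L) int32, rows in A,C,G,T order
    mapq: np.ndarray    # (L,) float32 mean mapping quality

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class PileupTable:
    chroms: dict[str, ChromPileup] = field(default_factory=dict)

    def depth(self, chrom: str) -> np.ndarray:
        return self.chroms[chrom].depth

    def mean_coverage(self) -> float:
        """Mean depth over covered positions (depth >= 1) only."""
        tot = n = 0
        for cp in self.chroms.values():
            d = cp.depth
            covered = d > 0
            tot += int(d[covered].sum())
            n += int(covered.sum())
        if n == 0:
            raise ParameterError("pileup table has no covered positions")
        return tot / n

    def to_frame(self, chromosomes: Mapping[str, str]) -> pd.DataFrame:
        rows = []
        for chrom, cp in self.chroms.items():
            seq = st.seq_array(chromosomes[chrom])
            covered = np.where(cp.depth > 0)[0]
            rows.append(pd.DataFrame({
                "chrom": chrom,
                "pos": covered,
                "ref": [chr(b) for b in seq[covered]],
                "A": cp.counts[0, covered], "C": cp.counts[1, covered],
                "G": cp.counts[2, covered], "T": cp.counts[3, covered],
                "mapq": cp.mapq[covered],
            }))
        df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["chrom", "pos", "ref", "A", "C", "G", "T", "mapq"])
        df["depth"] = df[list(BASES)].sum(axis=1)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   chrom_lengths: Mapping[str, int]) -> "PileupTable":
        table = cls()
        for chrom, length in chrom_lengths.items():
            cp = ChromPileup(np.zeros((4, length), np.int32),
                             np.zeros(length, np.float32))
            sub = df[df["chrom"] == chrom]
            pos = sub["pos"].to_numpy(np.int64)
            for i, b in enumerate(BASES):
                cp.counts[i, pos] = sub[b].to_numpy(np.int64)
            cp.mapq[pos] = sub["mapq"].to_numpy(float)
            table.chroms[chrom] = cp
        return table


@dataclass(frozen=True)
class Pileup:
    """One pileup row (the unit the single-site genotyper consumes)."""

    chromosome: str
    position: int
    ref: str
    counts: tuple[int, int, int, int]  # A, C, G, T
    mapq: float

    @property
    def depth(self) -> int:
        return sum(self.counts)


@dataclass
class VariantCall:
    chromosome: str
    position: int
    ref: str
    alt: str | None
    genotype: str
    depth: int
    mapq: float
    passed_filters: bool = False


def _genotype_from_counts(n_ref: int, n_alt: int, error_rate: float) -> str:
    """Maximum-likelihood diploid genotype for ref/alt read counts.

    Ties are broken toward hom_ref, then het.
    """
    le, l1e = math.log(error_rate), math.log1p(-error_rate)
    ll = (n_ref * l1e + n_alt * le,          # hom_ref
          (n_ref + n_alt) * math.log(0.5),   # het
          n_alt * l1e + n_ref * le)          # hom_alt
    return (HOM_REF, HET, HOM_ALT)[int(np.argmax(ll))]


def genotype_site(pileup: Pileup, error_rate: float = 0.01) -> VariantCall | None:
    if pileup.depth < 1:
        raise ParameterError("genotyping requires depth >= 1")
    if pileup.ref not in _BASE_INDEX:
        warnings.warn(f"reference base {pileup.ref!r} at "
                      f"{pileup.chromosome}:{pileup.position}; site skipped")
        return None
    ref_i = _BASE_INDEX[pileup.ref]
    n_ref = pileup.counts[ref_i]
    alts = [(c, i) for i, c in enumerate(pileup.counts) if i != ref_i]
    n_alt, alt_i = max(alts, key=lambda t: (t[0], -t[1]))
    if n_alt == 0:
        return VariantCall(pileup.chromosome, pileup.position, pileup.ref,
                           None, HOM_REF, pileup.depth, pileup.mapq)
    gt = _genotype_from_counts(n_ref, n_alt, error_rate)
    alt = BASES[alt_i] if gt != HOM_REF else None
    return VariantCall(pileup.chromosome, pileup.position, pileup.ref, alt,
                       gt, pileup.depth, pileup.mapq)


def call_variants(pileups: PileupTable, chromosomes: Mapping[str, str],
                  error_rate: float = 0.01) -> pd.DataFrame:
    """Vectorised genotyping; returns non-hom_ref calls only."""
    chromosomes = getattr(chromosomes, "chromosomes", chromosomes)
    le, l1e = math.log(error_rate), math.log1p(-error_rate)
    rows = []
    for chrom, cp in pileups.chroms.items():
        seq = st.seq_array(chromosomes[chrom])[:cp.counts.shape[1]]
        ref_i = np.full(seq.size, -1, np.int8)
        for i, b in enumerate(BASES):
            ref_i[seq == ord(b)] = i
        valid = ref_i >= 0
        depth = cp.depth
        counts = cp.counts
        pos_all = np.where((depth > 0) & valid)[0]
        if pos_all.size == 0:
            continue
        sub = counts[:, pos_all]
        n_ref = sub[ref_i[pos_all], np.arange(pos_all.size)]
        masked = sub.copy()
        masked[ref_i[pos_all], np.arange(pos_all.size)] = -1
        alt_i = masked.argmax(axis=0)
        n_alt = masked.max(axis=0)
        has_alt = n_alt > 0
        pos = pos_all[has_alt]
        if pos.size == 0:
            continue
        n_ref, n_alt, alt_i = n_ref[has_alt], n_alt[has_alt], alt_i[has_alt]
        ll = np.stack([n_ref * l1e + n_alt * le,
                       (n_ref + n_alt) * math.log(0.5),
                       n_alt * l1e + n_ref * le])
        gt_code = ll.argmax(axis=0)  # argmax takes the first max: hom_ref wins ties
        keep = gt_code > 0
        if not keep.any():
            continue
        pos, gt_code, alt_i = pos[keep], gt_code[keep], alt_i[keep]
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos,
            "ref": [BASES[i] for i in ref_i[pos]],
            "alt": [BASES[i] for i in alt_i],
            "genotype": np.where(gt_code == 1, HET, HOM_ALT),
            "depth": depth[pos],
            "mapq": cp.mapq[pos],
        }))
    cols = ["chrom", "pos", "ref", "alt", "genotype", "depth", "mapq"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)[cols]


def depth_window(mean_coverage: float, lower_frac: float = 1 / 3,
                 upper_frac: float = 1.75, floor_reads: int = 4) -> tuple[int, int]:
    """Depth acceptance window around the dataset's mean coverage.

    Lower bound: floor of ``mean * lower_frac``, never below ``floor_reads``;
    upper bound: round-half-up of ``mean * upper_frac``.
    """
    if mean_coverage <= 0:
        raise ParameterError("mean coverage must be positive")
    lo = max(floor_reads, math.floor(mean_coverage * lower_frac))
    hi = math.floor(mean_coverage * upper_frac + 0.5)
    if lo > hi:
        raise ParameterError(f"empty depth window ({lo}, {hi})")
    return lo, hi


def filter_variants(calls: pd.DataFrame, window: tuple[int, int],
                    min_mapq: float = 20) -> pd.DataFrame:
    """Keep non-hom_ref calls inside the depth window with adequate MAPQ."""
    lo, hi = window
    keep = ((calls["genotype"] != HOM_REF)
            & (calls["depth"] >= lo) & (calls["depth"] <= hi)
            & (calls["mapq"] >= min_mapq))
    out = calls[keep].copy()
    out["passed_filters"] = True
    return out.reset_index(drop=True)


@dataclass
class DatasetEvidence:
    """One SNP-evidence dataset: pileups, its passing variants, its window."""

    pileups: PileupTable
    variants: pd.DataFrame
    window: tuple[int, int]


def _pct(num: int, den: int) -> float:
    """Percentage at two decimals, round-half-up (reporting convention)."""
    if den == 0:
        return float("nan")
    q = Decimal(num) / Decimal(den) * 100
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CpgValidationReport:
    n_high_confidence: int
    tested_control: int
    snp_control: int
    tested_wgs: int
    snp_wgs: int
    co_covered_snp_union: int
    co_covered_snp_both: int
    excluded_total: int

    def percentages(self) -> dict[str, float]:
        return {
            "pct_tested_wgs": _pct(self.tested_wgs, self.n_high_confidence),
            "pct_snp_wgs": _pct(self.snp_wgs, self.tested_wgs),
            "pct_tested_control": _pct(self.tested_control, self.n_high_confidence),
            "pct_snp_control": _pct(self.snp_control, self.tested_control),
            "pct_snp_both_of_union": _pct(self.co_covered_snp_both,
                                          self.co_covered_snp_union),
        }


@dataclass
class CpgValidation:
    report: CpgValidationReport
    excluded: pd.DataFrame  # chrom, pos of SNP-bearing CpG sites (union)


def _site_masks(sites: pd.DataFrame, ev: DatasetEvidence):
    """(tested, snp) boolean masks over the CpG site table for one dataset.

    A combined CpG site (keyed at its plus-strand C position p) is tested
    if the pileup depth at p or p+1 falls inside the window; it carries a
    SNP if a passing variant overlaps p or p+1.
    """
    lo, hi = ev.window
    tested = np.zeros(len(sites), bool)
    snp = np.zeros(len(sites), bool)
    for chrom, idx in sites.groupby("chrom").indices.items():
        pos = sites["pos"].to_numpy(np.int64)[idx]
        if chrom in ev.pileups.chroms:
            depth = ev.pileups.depth(chrom)
            L = depth.size
            d1 = np.where(pos < L, depth[np.minimum(pos, L - 1)], 0)
            p2 = np.minimum(pos + 1, L - 1)
            d2 = np.where(pos + 1 < L, depth[p2], 0)
            tested[idx] = ((d1 >= lo) & (d1 <= hi)) | ((d2 >= lo) & (d2 <= hi))
        var_pos = ev.variants.loc[ev.variants["chrom"] == chrom, "pos"]
        vp = set(var_pos.to_numpy(np.int64).tolist())
        if vp:
            snp[idx] = np.array([p in vp or (p + 1) in vp for p in pos])
    return tested, snp


def validate_cpg_sites(cpg_sites: pd.DataFrame, control: DatasetEvidence,
                       wgs: DatasetEvidence) -> CpgValidation:
    """SNP validation of high-confidence CpG sites against both datasets.

    ``cpg_sites`` must carry ``chrom`` and ``pos`` (plus-strand C position
    of the combined site). The exclusion set is the union of SNP-bearing
    sites across datasets.
    """
    sites = cpg_sites[["chrom", "pos"]].reset_index(drop=True)
    if sites.empty:
        warnings.warn("empty CpG site set; empty validation report")
        return CpgValidation(CpgValidationReport(0, 0, 0, 0, 0, 0, 0, 0),
                             sites.copy())
    tested_c, snp_c = _site_masks(sites, control)
    tested_w, snp_w = _site_masks(sites, wgs)
    co = tested_c & tested_w
    excluded_mask = snp_c | snp_w
    report = CpgValidationReport(
        n_high_confidence=len(sites),
        tested_control=int(tested_c.sum()),
        snp_control=int(snp_c.sum()),
        tested_wgs=int(tested_w.sum()),
        snp_wgs=int(snp_w.sum()),
        co_covered_snp_union=int((co & (snp_c | snp_w)).sum()),
        co_covered_snp_both=int((co & snp_c & snp_w).sum()),
        excluded_total=int(excluded_mask.sum()),
    )
    return CpgValidation(report, sites[excluded_mask].reset_index(drop=True))


def validate_noncpg_sites(sites: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """Exclusion set for non-CpG cytosines.

    A non-CpG cytosine is excluded if a variant overlaps its own position,
    or if its 3'-adjacent position carries a variant whose alternate allele
    would create a CpG (alt G downstream of a plus-strand C; alt C upstream
    of a minus-strand cytosine, i.e. a genomic G).
    """
    out_mask = np.zeros(len(sites), bool)
    sites = sites.reset_index(drop=True)
    for chrom, idx in sites.groupby("chrom").indices.items():
        sub = variants[variants["chrom"] == chrom]
        vpos = set(sub["pos"].to_numpy(np.int64).tolist())
        galt = set(sub.loc[sub["alt"] == "G", "pos"].to_numpy(np.int64).tolist())
        calt = set(sub.loc[sub["alt"] == "C", "pos"].to_numpy(np.int64).tolist())
        pos = sites["pos"].to_numpy(np.int64)[idx]
        strand = sites["strand"].to_numpy()[idx]
        hit = np.array([
            p in vpos
            or (s == "+" and (p + 1) in galt)
            or (s == "-" and (p - 1) in calt)
            for p, s in zip(pos, strand)
        ])
        out_mask[idx] = hit
    return sites[out_mask].reset_index(drop=True)
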