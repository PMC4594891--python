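"""Genomic region sets, metagene profiles, dinucleotide densities and the
normality-dispatched group comparison.

Region conventions (0-based, half-open, orientation-aware):

* TSS window: 300 bp upstream to 200 bp downstream of the annotated TSS.
* gene body: the annotated gene span minus its 5' 5 % (avoids the TSS).
* CGS (CpG island shores): fixed-width flanks of each CGI, truncated at
  neighbouring CGIs and chromosome ends.
* introns: gene span minus exons; upstream10kb: 10 kb upstream of the TSS.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _seqtools as st
from .errors import ParameterError
from .exprcorr import spearman

REGION_COLS = ["chrom", "start", "end", "strand", "name", "provenance"]


def _frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=REGION_COLS)


def merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(iv):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(iv: tuple[int, int],
                       minus: list[tuple[int, int]]) -> list[tuple[int, int]]:
    pieces = [iv]
    for ms, me in sorted(minus):
        nxt = []
        for s, e in pieces:
            if me <= s or ms >= e:
                nxt.append((s, e))
                continue
            if ms > s:
                nxt.append((s, ms))
            if me < e:
                nxt.append((me, e))
        pieces = nxt
    return [p for p in pieces if p[1] > p[0]]


def tss_window(tss: int, strand: str, upstream: int = 300,
               downstream: int = 200) -> tuple[int, int]:
    if strand == "+":
        return tss - upstream, tss + downstream
    return tss - downstream, tss + upstream


def build_regions(genes, cgis, chrom_lengths, shore_width: int = 2000,
                  tss_upstream: int = 300, tss_downstream: int = 200,
                  body_exclusion: float = 0.05,
                  upstream_span: int = 10_000) -> dict[str, pd.DataFrame]:
    """Build the full region-set collection from gene and CGI annotation.

    ``genes`` is an iterable of objects with id/chromosome/strand/
    tss_position/exons; ``cgis`` an iterable of (chrom, start, end).
    Intervals are clipped to chromosome bounds (with a warning when a
    feature runs off the end).
    """
    chrom_lengths = {c: (len(v) if isinstance(v, str) else int(v))
                     for c, v in dict(chrom_lengths).items()}

    def clip(chrom, s, e, what):
        L = chrom_lengths[chrom]
        if s < 0 or e > L:
            warnings.warn(f"{what} truncated at bounds of {chrom}")
        return max(0, s), min(L, e)

    tss_rows, body_rows, exon_rows, intron_rows, up_rows = [], [], [], [], []
    for g in genes:
        s, e = tss_window(g.tss_position, g.strand, tss_upstream, tss_downstream)
        s, e = clip(g.chromosome, s, e, f"TSS window of {g.id}")
        tss_rows.append((g.chromosome, s, e, g.strand, "TSS_window", g.id))
        span_s = min(x[0] for x in g.exons)
        span_e = max(x[1] for x in g.exons)
        cut = int((span_e - span_s) * body_exclusion)
        if g.strand == "+":
            bs, be = span_s + cut, span_e
        else:
            bs, be = span_s, span_e - cut
        body_rows.append((g.chromosome, bs, be, g.strand, "gene_body", g.id))
        for xs, xe in g.exons:
            exon_rows.append((g.chromosome, xs, xe, g.strand, "exon", g.id))
        for is_, ie in subtract_intervals((span_s, span_e), list(g.exons)):
            intron_rows.append((g.chromosome, is_, ie, g.strand, "intron", g.id))
        if g.strand == "+":
            us, ue = g.tss_position - upstream_span, g.tss_position
        else:
            us, ue = g.tss_position + 1, g.tss_position + 1 + upstream_span
        us, ue = clip(g.chromosome, us, ue, f"upstream10kb of {g.id}")
        up_rows.append((g.chromosome, us, ue, g.strand, "upstream10kb", g.id))

    cgi_rows, shore_rows = [], []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    cgis = list(cgis)
    for chrom, s, e in cgis:
        by_chrom.setdefault(chrom, []).append((s, e))
    for i, (chrom, s, e) in enumerate(cgis):
        s, e = clip(chrom, s, e, "CGI")
        cgi_rows.append((chrom, s, e, ".", "CGI", f"cgi_{i}"))
        others = [iv for iv in by_chrom[chrom]]
        for fs, fe in ((s - shore_width, s), (e, e + shore_width)):
            fs, fe = clip(chrom, fs, fe, "CGS")
            for ps, pe in subtract_intervals((fs, fe), others):
                shore_rows.append((chrom, ps, pe, ".", "CGS", f"cgi_{i}"))

    return {
        "TSS_window": _frame(tss_rows),
        "gene_body": _frame(body_rows),
        "exon": _frame(exon_rows),
        "intron": _frame(intron_rows),
        "upstream10kb": _frame(up_rows),
        "CGI": _frame(cgi_rows),
        "CGS": _frame(shore_rows),
    }


def _membership(positions: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask: which positions fall in any (merged) interval."""
    merged = merge_intervals(list(zip(intervals["start"], intervals["end"])))
    if not merged:
        return np.zeros(positions.size, bool)
    starts = np.array([s for s, _ in merged])
    ends = np.array([e for _, e in merged])
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = idx >= 0
    mask = np.zeros(positions.size, bool)
    mask[ok] = positions[ok] < ends[idx[ok]]
    return mask


def assign_sites(sites: pd.DataFrame,
                 regions: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Label each site with every region set it overlaps.

    Adds one boolean column per region name plus an ``intergenic`` flag
    (no feature at all).
    """
    out = sites.reset_index(drop=True).copy()
    for name, reg in regions.items():
        mask = np.zeros(len(out), bool)
        for chrom, idx in out.groupby("chrom").indices.items():
            sub = reg[reg["chrom"] == chrom]
            if len(sub):
                mask[idx] = _membership(out["pos"].to_numpy(np.int64)[idx], sub)
        out[name] = mask
    out["intergenic"] = ~out[list(regions)].any(axis=1)
    return out


def metagene_profile(sites: pd.DataFrame, anchors, window: tuple[int, int] = (-2000, 2000),
                     bin_size: int = 100) -> pd.DataFrame:
    """Mean methylation by oriented offset bin around a set of anchors.

    ``anchors`` is an iterable of (chrom, position, strand). Offsets are
    measured in transcription orientation; each bin's value is the
    unweighted mean of site levels falling in it, NaN where empty.
    """
    lo, hi = window
    if (hi - lo) % bin_size != 0:
        raise ParameterError("window must be divisible by bin_size")
    anchors = list(anchors)
    if not anchors:
        raise ParameterError("at least one anchor required")
    edges = np.arange(lo, hi + bin_size, bin_size)
    sums = np.zeros(edges.size - 1)
    counts = np.zeros(edges.size - 1, np.int64)
    by_chrom = {c: g.sort_values("pos") for c, g in sites.groupby("chrom")}
    for chrom, apos, strand in anchors:
        if chrom not in by_chrom:
            continue
        sub = by_chrom[chrom]
        pos = sub["pos"].to_numpy(np.int64)
        lev = sub["level"].to_numpy(float)
        if strand == "+":
            pmin, pmax = apos + lo, apos + hi
        else:
            pmin, pmax = apos - hi + 1, apos - lo + 1
        i0, i1 = np.searchsorted(pos, [pmin, pmax])
        if i1 <= i0:
            continue
        off = pos[i0:i1] - apos if strand == "+" else apos - pos[i0:i1]
        keep = (off >= lo) & (off < hi)
        b = (off[keep] - lo) // bin_size
        np.add.at(sums, b, lev[i0:i1][keep])
        np.add.at(counts, b, 1)
    mean = np.divide(sums, counts, out=np.full(sums.shape, np.nan),
                     where=counts > 0)
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                         "mean_level": mean, "n_sites": counts})


def dinucleotide_density(chromosomes, regions: pd.DataFrame,
                         dinuc: str = "CG") -> pd.DataFrame:
    """Per-region dinucleotide density, normalised to counts per 100 bp.

    Counts plus-strand start positions of the dinucleotide inside each
    interval (CpG is strand-symmetric; TpG/ApG are counted as written).
    """
    chromosomes = getattr(chromosomes, "chromosomes", chromosomes)
    rows = []
    arrs = {}
    for _, r in regions.iterrows():
        length = r["end"] - r["start"]
        if length <= 0:
            warnings.warn(f"zero-length region {r['name']}:{r['provenance']} skipped")
            continue
        if r["chrom"] not in arrs:
            arrs[r["chrom"]] = st.seq_array(chromosomes[r["chrom"]])
        arr = arrs[r["chrom"]]
        starts = st.dinuc_starts(arr[r["start"]:min(r["end"] + 1, arr.size)], dinuc)
        count = int((starts < length).sum())
        rows.append({"chrom": r["chrom"], "start": r["start"], "end": r["end"],
                     "name": r["name"], "provenance": r["provenance"],
                     "dinuc": dinuc.upper().replace("CG", "CpG").replace("TG", "TpG").replace("AG", "ApG"),
                     "count": count, "density": 100.0 * count / length})
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    test: str
    statistic: float
    pvalue: float
    normality_p: tuple[float, float] | None
    variance_p: float | None
    notes: str = ""


def _normality_p(x: np.ndarray) -> float:
    # Shapiro-Wilk up to its recommended size, Kolmogorov-Smirnov beyond
    if x.size <= 5000:
        return float(stats.shapiro(x).pvalue)
    z = (x - x.mean()) / x.std(ddof=1)
    return float(stats.kstest(z, "norm").pvalue)


def compare_groups(values_a, values_b, paired: bool = False,
                   alpha: float = 0.05,
                   alternative: str = "two-sided") -> GroupComparison:
    """Statistical dispatch for two-group comparisons.

    Both groups normal (Shapiro-Wilk for n <= 5000, else KS, at p > alpha)
    -> Student's t-test, pooling variances when an F-test accepts equality;
    otherwise the Wilcoxon path (signed-rank when paired, rank-sum when
    not). Constant input short-circuits to the nonparametric path.
    ``alternative`` follows the scipy convention ("greater" tests whether
    the first group exceeds the second).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 3 or b.size < 3:
        raise ParameterError("each group needs n >= 3")
    if paired and a.size == b.size and np.array_equal(a, b):
        warnings.warn("identical paired samples; all differences zero, p = 1")
        return GroupComparison("wilcoxon signed-rank", 0.0, 1.0, None, None,
                               "all paired differences zero")
    notes = ""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        notes = "constant input; normality undefined, nonparametric path"
        warnings.warn(notes)
        norm = None
    else:
        norm = (_normality_p(a), _normality_p(b))
    if norm is not None and norm[0] > alpha and norm[1] > alpha:
        f = float(np.var(a, ddof=1) / np.var(b, ddof=1))
        fp = 2 * min(stats.f.cdf(f, a.size - 1, b.size - 1),
                     stats.f.sf(f, a.size - 1, b.size - 1))
        fp = float(min(1.0, fp))
        if paired:
            res = stats.ttest_rel(a, b, alternative=alternative)
            name = "paired t-test"
        else:
            equal_var = fp > alpha
            res = stats.ttest_ind(a, b, equal_var=equal_var,
                                  alternative=alternative)
            name = "t-test" if equal_var else "Welch t-test"
        return GroupComparison(name, float(res.statistic), float(res.pvalue),
                               norm, fp, notes)
    if paired:
        try:
            res = stats.wilcoxon(a, b, alternative=alternative)
        except ValueError:
            warnings.warn("all paired differences zero; p undefined, reporting 1.0")
            return GroupComparison("wilcoxon signed-rank", 0.0, 1.0, norm, None,
                                   notes + " all differences zero")
        name = "wilcoxon signed-rank"
    else:
        res = stats.mannwhitneyu(a, b, alternative=alternative)
        name = "wilcoxon rank-sum"
    return GroupComparison(name, float(res.statistic), float(res.pvalue),
                           norm, None, notes)


def chromosome_summary(levels: pd.DataFrame, chrom_class: dict[str, str],
                       methylated_threshold: float = 0.10):
    """Per-chromosome methylation summary and the X-vs-autosome comparison.

    ``levels`` carries chrom/pos/level and optionally a ``tissue`` column.
    Percentages are on the 0-100 scale; ``pct_unmethylated`` counts sites
    at exactly 0, ``pct_methylated`` sites above the context threshold
    (0.10 for CpG, 0.01 for non-CpG).
    """
    df = levels.copy()
    if "tissue" not in df:
        df["tissue"] = "all"
    rows = []
    for (tissue, chrom), grp in df.groupby(["tissue", "chrom"]):
        lv = grp["level"].to_numpy(float)
        rows.append({
            "tissue": tissue, "chrom": chrom,
            "chrom_class": chrom_class.get(chrom, "autosome"),
            "n_sites": lv.size,
            "mean_level_pct": 100 * lv.mean(),
            "pct_unmethylated": 100 * (lv == 0).mean(),
            "pct_methylated": 100 * (lv > methylated_threshold).mean(),
        })
    summary = pd.DataFrame(rows)
    comparisons = {}
    for tissue, grp in df.groupby("tissue"):
        x = grp.loc[grp["chrom"].map(chrom_class).eq("X"), "level"]
        auto = grp.loc[grp["chrom"].map(chrom_class).ne("X"), "level"]
        if len(x) >= 3 and len(auto) >= 3:
            # elevation is a directional claim: one-sided X > autosomes
            comparisons[tissue] = compare_groups(x, auto,
                                                 alternative="greater")
    return summary, comparisons


def coverage_bias_check(covered_sites: pd.DataFrame, chromosomes) -> dict:
    """Spearman correlation between per-chromosome covered-site counts and
    total genomic CpG counts (chromosomal coverage-bias check)."""
    chromosomes = getattr(chromosomes, "chromosomes", chromosomes)
    names = sorted(chromosomes)
    if len(names) < 3:
        raise ParameterError("need at least 3 chromosomes")
    covered = covered_sites.groupby("chrom").size()
    x = [st.cpg_starts(st.seq_array(chromosomes[c])).size for c in names]
    y = [int(covered.get(c, 0)) for c in names]
    return spearman(x, y)
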