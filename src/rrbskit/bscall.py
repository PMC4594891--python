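"""Bisulfite read placement and per-cytosine methylation calling.

Reads are aligned in three-letter space against the reduced genome: the
read is C->T collapsed and compared to the C->T forward index, and to the
C->T collapse of each fragment's reverse complement (equivalent to a G->A
reverse index). Only unique best placements within the mismatch budget are
kept. Calling then counts, per reference cytosine, strand-appropriate
methylated (C on plus / G on minus in fragment orientation) versus
converted (T / A) read bases; any other read base is non-informative.
"""
from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import _seqtools as st
from .errors import ParameterError, UndefinedResultError
from .rrbs_reduce import ReducedGenome

UNMAPPED = "unmapped"
AMBIGUOUS = "ambiguous"
ALIGNED = "aligned"


@dataclass(frozen=True)
class BsAlignment:
    """A unique read placement, stored in fragment (plus-strand) orientation."""

    read_id: str
    frag_index: int
    strand: str  # strand of origin: '+' or '-'
    offset: int  # fragment-local start of the covered interval
    length: int
    mismatches: int
    seq_frag: bytes  # read bases re-oriented to fragment coordinates


@dataclass(frozen=True)
class AlignResult:
    status: str
    alignment: BsAlignment | None = None
    reason: str = ""


class BsAligner:
    """Unique bisulfite matcher over a reduced genome.

    Seeds are exact k-mer lookups in converted space; if the exact seed
    misses, all single-substitution neighbours of the seed are probed
    (``seed_mm = 1``). Candidates are scored by total mismatches in
    converted space; at most ``read_mm`` mismatches are allowed and ties
    for the best score are reported as ambiguous.
    """

    def __init__(self, reduced: ReducedGenome, seed_len: int = 20,
                 seed_mm: int = 1, read_mm: int = 2):
        if len(reduced) == 0:
            raise ParameterError("empty reduced genome")
        self.reduced = reduced
        self.seed_len = seed_len
        self.seed_mm = seed_mm
        self.read_mm = read_mm
        # space 0: C->T of the fragment; space 1: C->T of its reverse complement
        self._spaces = (
            reduced.fwd_c2t,
            [st.revcomp(s).translate(st.C2T) for s in reduced.sequences],
        )
        self._index: dict[bytes, list[tuple[int, int, int]]] = defaultdict(list)
        for space_id, seqs in enumerate(self._spaces):
            for i, s in enumerate(seqs):
                for off in range(len(s) - seed_len + 1):
                    self._index[s[off:off + seed_len]].append((space_id, i, off))

    def align(self, read_id: str, seq: bytes) -> AlignResult:
        seq = st.as_bytes(seq)
        L = len(seq)
        if L < self.seed_len:
            return AlignResult(UNMAPPED, reason="shorter than seed")
        collapsed = seq.translate(st.C2T)
        seed = collapsed[:self.seed_len]
        candidates = list(self._index.get(seed, ()))
        if not candidates and self.seed_mm >= 1:
            for j in range(self.seed_len):
                for b in b"AGT":  # converted space holds no C
                    if seed[j] == b:
                        continue
                    variant = seed[:j] + bytes([b]) + seed[j + 1:]
                    candidates.extend(self._index.get(variant, ()))
        best: list[tuple[int, int, int, int]] = []  # (mm, space, frag, off)
        seen = set()
        for space_id, i, off in candidates:
            if (space_id, i, off) in seen:
                continue
            seen.add((space_id, i, off))
            ref = self._spaces[space_id][i]
            if off + L > len(ref):
                continue
            window = ref[off:off + L]
            if window == collapsed:
                mm = 0
            else:
                diff = np.frombuffer(window, np.uint8) != np.frombuffer(collapsed, np.uint8)
                if int(diff[:self.seed_len].sum()) > self.seed_mm:
                    continue
                mm = int(diff.sum())
                if mm > self.read_mm:
                    continue
            best.append((mm, space_id, i, off))
        if not best:
            return AlignResult(UNMAPPED, reason="no placement within mismatch budget")
        best.sort()
        if len(best) > 1 and best[1][0] == best[0][0]:
            return AlignResult(AMBIGUOUS, reason="multiple equally good placements")
        mm, space_id, i, off = best[0]
        frag_len = len(self.reduced.sequences[i])
        if space_id == 0:
            aln = BsAlignment(read_id, i, "+", off, L, mm, seq)
        else:
            aln = BsAlignment(read_id, i, "-", frag_len - off - L, L, mm,
                              st.revcomp(seq))
        return AlignResult(ALIGNED, aln)


def align_bs_read(read_id: str, seq: bytes, reduced: ReducedGenome | BsAligner,
                  seed_len: int = 20, seed_mm: int = 1, read_mm: int = 2) -> AlignResult:
    """One-shot convenience wrapper; builds a throwaway index unless given
    an existing :class:`BsAligner`."""
    aligner = reduced if isinstance(reduced, BsAligner) else BsAligner(
        reduced, seed_len, seed_mm, read_mm)
    return aligner.align(read_id, seq)


def clip_overlap(mate1: tuple[int, int], mate2: tuple[int, int],
                 same_fragment: bool = True):
    """Remove the overlap between paired mates from mate2's coverage.

    Returns ``(mate1, mate2_pieces)`` where the pieces are the (possibly
    split, possibly empty) remainder of mate2 after subtracting mate1, so
    overlapping bases are counted exactly once (mate1 wins).
    """
    if not same_fragment:
        warnings.warn("mates on different fragments; no clipping applied")
        return mate1, [mate2]
    s1, e1 = mate1
    s2, e2 = mate2
    pieces = []
    if s2 < s1:
        pieces.append((s2, min(e2, s1)))
    if e2 > e1:
        pieces.append((max(s2, e1), e2))
    return mate1, [(s, e) for s, e in pieces if e > s]


def _context_maps(chromosomes: Mapping[str, str], cache: dict) -> dict:
    for name in chromosomes:
        if name not in cache:
            arr = st.seq_array(chromosomes[name])
            ctx_plus = np.full(arr.size, -1, np.int8)
            ctx_minus = np.full(arr.size, -1, np.int8)
            pp, pc, mp, mc = st.cytosine_contexts(arr)
            ctx_plus[pp] = pc
            ctx_minus[mp] = mc
            cache[name] = (ctx_plus, ctx_minus)
    return cache


def call_methylation(alignments: Iterable[BsAlignment], reduced: ReducedGenome,
                     chromosomes: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-strand methylation table from unique alignments.

    Context is assigned from the reference chromosome (so fragment-edge
    cytosines still get their true context); sites with unknown context
    (N neighbour or chromosome end) are excluded.
    """
    if chromosomes is not None:
        chromosomes = getattr(chromosomes, "chromosomes", chromosomes)
    ctx_cache: dict = {}
    by_frag: dict[int, list[BsAlignment]] = defaultdict(list)
    for a in alignments:
        by_frag[a.frag_index].append(a)

    out = {k: [] for k in ("chrom", "pos", "strand", "context", "meth", "total")}
    for i, group in by_frag.items():
        frag = reduced.fragments[i]
        arr = st.seq_array(reduced.sequences[i])
        L = arr.size
        ref_c = np.where(arr == st.C)[0]
        ref_g = np.where(arr == st.G)[0]
        meth_p = np.zeros(L, np.int64)
        tot_p = np.zeros(L, np.int64)
        meth_m = np.zeros(L, np.int64)
        tot_m = np.zeros(L, np.int64)
        by_shape: dict[tuple, list[BsAlignment]] = defaultdict(list)
        for a in group:
            by_shape[(a.strand, a.offset, a.length)].append(a)
        for (strand, off, rlen), alns in by_shape.items():
            block = np.frombuffer(b"".join(a.seq_frag for a in alns),
                                  np.uint8).reshape(len(alns), rlen)
            if strand == "+":
                cols = ref_c[(ref_c >= off) & (ref_c < off + rlen)]
                sub = block[:, cols - off]
                meth_p[cols] += (sub == st.C).sum(0)
                tot_p[cols] += ((sub == st.C) | (sub == st.T)).sum(0)
            else:
                cols = ref_g[(ref_g >= off) & (ref_g < off + rlen)]
                sub = block[:, cols - off]
                meth_m[cols] += (sub == st.G).sum(0)
                tot_m[cols] += ((sub == st.G) | (sub == st.A)).sum(0)
        if chromosomes is not None:
            ctx_plus, ctx_minus = _context_maps(
                {frag.chromosome: chromosomes[frag.chromosome]}, ctx_cache
            )[frag.chromosome]
            ctx_p = ctx_plus[frag.start:frag.end]
            ctx_m = ctx_minus[frag.start:frag.end]
        else:
            pp, pc, mp, mc = st.cytosine_contexts(arr)
            ctx_p = np.full(L, -1, np.int8)
            ctx_m = np.full(L, -1, np.int8)
            ctx_p[pp] = pc
            ctx_m[mp] = mc
        for strand, tot, meth, ctx in (("+", tot_p, meth_p, ctx_p),
                                       ("-", tot_m, meth_m, ctx_m)):
            covered = np.where((tot > 0) & (ctx >= 0) & (ctx != st.UNKNOWN))[0]
            if covered.size == 0:
                continue
            out["chrom"].append(np.array([frag.chromosome] * covered.size, dtype=object))
            out["pos"].append(frag.start + covered)
            out["strand"].append(np.array([strand] * covered.size, dtype=object))
            out["context"].append(ctx[covered])
            out["meth"].append(meth[covered])
            out["total"].append(tot[covered])
    if not out["pos"]:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context",
                                     "meth", "total", "level"])
    df = pd.DataFrame({
        "chrom": np.concatenate(out["chrom"]),
        "pos": np.concatenate(out["pos"]).astype(np.int64),
        "strand": np.concatenate(out["strand"]),
        "context": pd.Categorical.from_codes(
            np.concatenate(out["context"]).astype(np.int8),
            categories=list(st.CONTEXT_LABELS)),
        "meth": np.concatenate(out["meth"]),
        "total": np.concatenate(out["total"]),
    })
    # one fragment per locus, but be safe if fragments ever overlap
    df = (df.groupby(["chrom", "pos", "strand", "context"], observed=True,
                     as_index=False)[["meth", "total"]].sum())
    df = df[df["total"] > 0].reset_index(drop=True)
    df["level"] = df["meth"] / df["total"]
    return df.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def combine_cpg_strands(table: pd.DataFrame) -> pd.DataFrame:
    """Sum plus- and minus-strand counts of each CpG into one record.

    The combined record is keyed at the plus-strand C position (the minus
    strand's cytosine sits one base downstream); strand is reported as
    ``*``. Non-CpG records pass through unchanged.
    """
    if table.empty:
        return table.copy()
    cpg = table[table["context"] == "CpG"].copy()
    rest = table[table["context"] != "CpG"].copy()
    key = cpg["pos"].to_numpy(np.int64).copy()
    key[(cpg["strand"] == "-").to_numpy()] -= 1
    cpg["pos"] = key
    combined = (cpg.groupby(["chrom", "pos"], as_index=False)[["meth", "total"]]
                .sum())
    combined["strand"] = "*"
    combined["context"] = "CpG"
    out = pd.concat([combined, rest], ignore_index=True)
    out["context"] = pd.Categorical(out["context"], categories=list(st.CONTEXT_LABELS))
    out["level"] = out["meth"] / out["total"]
    cols = ["chrom", "pos", "strand", "context", "meth", "total", "level"]
    return out[cols].sort_values(["chrom", "pos", "strand"], ignore_index=True)


KEY_COLS = ["chrom", "pos", "strand", "context"]


@dataclass
class SiteFilterResult:
    """Depth pivot plus the two site sets the minimum-depth rule defines."""

    depth: pd.DataFrame  # index: site key, columns: samples, values: total reads
    high_confidence: pd.Index  # covered >= min_depth in at least one sample
    shared: pd.Index  # covered >= min_depth in every sample

    def shared_frame(self) -> pd.DataFrame:
        return self.shared.to_frame(index=False)


def filter_sites(tables: Mapping[str, pd.DataFrame], min_depth: int = 10) -> SiteFilterResult:
    """Apply the per-site minimum-depth rule across samples."""
    if min_depth < 1:
        raise ParameterError("min_depth must be >= 1")
    if not tables:
        raise ParameterError("at least one sample required")
    pieces = []
    for sample, df in tables.items():
        d = df.set_index(KEY_COLS)["total"].rename(sample)
        pieces.append(d)
    depth = pd.concat(pieces, axis=1).fillna(0).astype(np.int64)
    high = depth.index[(depth >= min_depth).any(axis=1)]
    shared = depth.index[(depth >= min_depth).all(axis=1)]
    return SiteFilterResult(depth, high, shared)


def estimate_conversion_rate(table: pd.DataFrame, min_informative: int = 1000) -> float:
    """Bisulfite conversion rate from non-CpG read-bases.

    Assumes true non-CpG methylation ~ 0, so every unconverted non-CpG
    read-base is attributed to incomplete conversion; with genuinely
    methylated non-CpG cytosines the estimate is biased low by roughly the
    mean non-CpG methylation level.
    """
    noncpg = table[table["context"].isin(["CHG", "CHH"])]
    total = int(noncpg["total"].sum())
    meth = int(noncpg["meth"].sum())
    if total < min_informative:
        raise UndefinedResultError(
            f"only {total} informative non-CpG read-bases (< {min_informative})")
    converted = total - meth
    return converted / total
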