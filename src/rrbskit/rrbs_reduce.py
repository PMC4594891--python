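"""In-silico MspI digestion and reduced-representation genome construction.

MspI is methylation-insensitive and cuts C^CGG. RRBS libraries sequence
size-selected digestion fragments, so the effective ("reduced") reference is
the set of fragments within a length window, indexed in bisulfite-converted
three-letter space: a C->T converted forward index and a G->A converted
reverse index per fragment.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import _seqtools as st
from .errors import ParameterError, SizingError


@dataclass(frozen=True)
class Fragment:
    """One digestion fragment, 0-based half-open on its chromosome."""

    chromosome: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def digest(sequence, site: str = "CCGG") -> list[int]:
    """Return the ordered cut positions of a restriction site in a sequence.

    The enzyme cuts one base into the site (C^CGG for MspI), so every
    occurrence at offset ``i`` yields a cut at ``i + 1``. Overlapping
    occurrences each yield a cut; N bases never match the site, so no cut
    is ever placed across an N.
    """
    seq = st.as_bytes(sequence)
    target = site.upper().encode()
    cuts: list[int] = []
    i = seq.find(target)
    while i != -1:
        cuts.append(i + 1)
        i = seq.find(target, i + 1)
    return cuts


def fragments_from_cuts(chromosome: str, length: int, cuts: list[int]) -> list[Fragment]:
    """Turn cut positions into the full disjoint fragment tiling of a chromosome."""
    bounds = [0] + sorted(set(cuts)) + [length]
    return [
        Fragment(chromosome, s, e)
        for s, e in zip(bounds[:-1], bounds[1:])
        if e > s
    ]


def size_select(fragments, min_len: int = 20, max_len: int = 180):
    """Retain fragments with ``min_len <= length <= max_len`` (both inclusive)."""
    if min_len > max_len:
        raise ParameterError(f"min_len {min_len} > max_len {max_len}")
    return [f for f in fragments if min_len <= f.length <= max_len]


@dataclass
class ReducedGenome:
    """Size-selected fragments plus their bisulfite-converted indexes.

    ``fwd_c2t`` carries no C, ``rev_g2a`` no G; both are stored in fragment
    (plus-strand) orientation. ``to_genomic`` maps fragment-local offsets
    back to chromosome coordinates.
    """

    fragments: list[Fragment]
    sequences: list[bytes]
    fwd_c2t: list[bytes] = field(repr=False)
    rev_g2a: list[bytes] = field(repr=False)

    def __len__(self) -> int:
        return len(self.fragments)

    def to_genomic(self, frag_index: int, local_pos: int) -> tuple[str, int]:
        frag = self.fragments[frag_index]
        if not 0 <= local_pos < frag.length:
            raise IndexError(f"local position {local_pos} outside fragment {frag}")
        return frag.chromosome, frag.start + local_pos

    def total_length(self) -> int:
        return sum(f.length for f in self.fragments)


def build_reduced_genome(genome, min_len: int = 20, max_len: int = 180,
                         site: str = "CCGG") -> ReducedGenome:
    """Digest a genome, size-select, and build the converted indexes.

    ``genome`` is either a mapping of chromosome name -> sequence string or
    any object with a ``chromosomes`` attribute holding such a mapping.
    """
    chromosomes: Mapping[str, str] = getattr(genome, "chromosomes", genome)
    fragments: list[Fragment] = []
    for name in chromosomes:
        seq = st.as_bytes(chromosomes[name])
        cuts = digest(seq, site)
        fragments.extend(size_select(fragments_from_cuts(name, len(seq), cuts),
                                     min_len, max_len))
    sequences = [st.as_bytes(chromosomes[f.chromosome])[f.start:f.end]
                 for f in fragments]
    fwd = [s.translate(st.C2T) for s in sequences]
    rev = [s.translate(st.G2A) for s in sequences]
    return ReducedGenome(fragments, sequences, fwd, rev)


def cpg_enrichment(reduced: ReducedGenome, genome) -> dict:
    """Compare the CpG fraction captured by retained fragments with the
    genome-length fraction retained — the defining enrichment of RRBS."""
    chromosomes: Mapping[str, str] = getattr(genome, "chromosomes", genome)
    total_len = sum(len(chromosomes[c]) for c in chromosomes)
    total_cpg = sum(st.cpg_starts(st.seq_array(chromosomes[c])).size
                    for c in chromosomes)
    if total_len == 0 or total_cpg == 0:
        raise SizingError("empty genome")
    kept_len = reduced.total_length()
    kept_cpg = sum(st.cpg_starts(st.seq_array(s)).size for s in reduced.sequences)
    return {
        "length_fraction": kept_len / total_len,
        "cpg_fraction": kept_cpg / total_cpg,
    }
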