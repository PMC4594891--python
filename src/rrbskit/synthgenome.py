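"""Synthetic genome, methylome and sequencing-data generator.

The simulator builds a small multi-chromosome genome (autosomes plus an
optional X) carrying the statistical structure the downstream analysis
assumes, and simulates RRBS reads, targeted-control and WGS pileups,
allelic RNA counts and an FPKM expression table from it:

* CpG islands (CGIs) with several-fold elevated CpG density;
* bimodal CpG methylation, hypomethylated in CGIs and in a dip centred at
  gene transcription start sites (TSS), anticoupled to expression;
* low non-CpG methylation with CHG above CHH;
* X-chromosome CpG hypermethylation in the "female" methylome only
  (X inactivation), absent in the "male" one;
* heterozygous SNPs enriched for C->T at CpG sites (5-methylcytosine
  deamination), plus CpG-creating variants;
* expression positively coupled to TSS CpG density and negatively to TpG
  density, produced mechanistically by rewriting CpG -> TpG (and a smaller
  ApG fraction) in promoters of low-expression genes;
* planted allele-specific and mono-allelic expression for a subset of
  genes, and per-tissue methylation effects at a subset of CpG sites.

Truth-level randomness derives from ``truth_seed`` so that two simulated
"individuals" (different ``seed``) can share one planted biology while
their reads and pileups stay independent.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seqtools as st
from .errors import ParameterError, SizingError
from .rrbs_reduce import ReducedGenome, build_reduced_genome
from .snpfilter import BASES, ChromPileup, PileupTable

TISSUES = ("fat", "heart", "kidney", "liver", "lung",
           "lymph_node", "muscle", "spleen")

_BASE_LOOKUP = np.frombuffer(b"ACGT", np.uint8)


@dataclass
class SimConfig:
    """Stated world of the simulation; defaults follow the study design
    where it states a value and field-realistic choices elsewhere."""

    n_autosomes: int = 2
    x_present: bool = True
    sex: str = "female"
    chrom_length: int = 850_000
    chrom_length_taper: float = 0.8
    n_genes: int = 340
    gene_length: tuple[int, int] = (1_500, 2_600)
    n_cgis: int = 290
    cgi_length: tuple[int, int] = (400, 1_200)
    cgi_cpg_token_prob: float = 0.3
    background_cpg_depletion: float = 0.35
    cgi_at_tss_fraction: float = 0.85
    tss_dip_halfwidth: int = 1_000
    conversion_rate: float = 0.9427
    sequencing_error: float = 0.0
    rrbs_depth_target: float = 20.0
    wgs_mean_coverage: float = 25.0
    control_mean_coverage: float = 12.7
    gc_bias_k: float = 0.1
    pileup_error_rate: float = 0.002
    low_mapq_fraction: float = 0.01
    library_insert_range: tuple[int, int] = (30, 160)
    reduced_genome_range: tuple[int, int] = (20, 180)
    fraction_zero_expression: float = 0.2757
    fraction_low_expression_with_tpg_replacement: float = 0.7
    tpg_replace_prob: float = 0.5
    apg_replace_prob: float = 0.1
    fpkm_log_mean: float = 1.2
    fpkm_log_sd: float = 1.8
    fpkm_noise_sigma: float = 0.2
    cpg_snp_fraction: float = 0.005
    noncpg_snp_fraction: float = 0.001
    creates_cpg_count: int = 150
    n_ase_genes: int = 20
    n_monoallelic_genes: int = 5
    n_nonase_het_genes: int = 40
    snps_per_ase_gene: int = 2
    ase_imbalance: float = 0.8
    ase_rna_depth: float = 50.0
    chg_meth_mean: float = 0.0055
    chh_meth_mean: float = 0.003
    tissue_variable_fraction: float = 0.05
    tissue_effect_low: float = 0.03
    tissue_effect_high: float = 0.80
    tissues: tuple[str, ...] = TISSUES
    seed: int = 0
    truth_seed: int | None = None

    def __post_init__(self):
        if not 0.9 < self.conversion_rate <= 1.0:
            raise ParameterError("conversion_rate must lie in (0.9, 1]")
        for name in ("rrbs_depth_target", "wgs_mean_coverage",
                     "control_mean_coverage"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_autosomes < 1:
            raise ParameterError("need at least one autosome")
        if self.sex not in ("female", "male"):
            raise ParameterError("sex must be 'female' or 'male'")

    @property
    def effective_truth_seed(self) -> int:
        return self.seed if self.truth_seed is None else self.truth_seed


def _rng(stream: int, seed: int) -> np.random.Generator:
    # independent, order-insensitive stream per operation
    return np.random.default_rng([stream, seed])


@dataclass
class GeneModel:
    id: str
    chromosome: str
    strand: str
    tss_position: int
    exons: list[tuple[int, int]]
    true_fpkm: float = 0.0
    ase_class: str = "none"
    ase_alt_prob: float = 0.5
    het_snps: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def validate(self):
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ParameterError(f"gene {self.id}: exons unsorted/overlapping")
        five_prime = self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1
        if self.tss_position != five_prime:
            raise ParameterError(f"gene {self.id}: TSS != 5' end of first exon")


@dataclass
class GenomeModel:
    chromosomes: dict[str, str]
    chrom_class: dict[str, str]
    genes: list[GeneModel]
    cgis: list[tuple[str, int, int]]
    seed: int

    def validate(self):
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ParameterError("chromosome names must be unique")
        n_x = sum(1 for c in self.chrom_class.values() if c == "X")
        n_auto = sum(1 for c in self.chrom_class.values() if c == "autosome")
        if n_auto < 1 or n_x > 1:
            raise ParameterError("need >= 1 autosome and at most one X")
        for g in self.genes:
            g.validate()
            L = len(self.chromosomes[g.chromosome])
            if not (0 <= g.span[0] < g.span[1] <= L):
                raise ParameterError(f"gene {g.id} outside chromosome")
        for chrom, s, e in self.cgis:
            if not (0 <= s < e <= len(self.chromosomes[chrom])):
                raise ParameterError("CGI outside chromosome")

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes.items()}


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASE_LOOKUP[rng.integers(0, 4, length)]


def _cgi_sequence(rng: np.random.Generator, length: int, cg_prob: float) -> np.ndarray:
    """GC-rich sequence with planted CG dinucleotides (token sampling)."""
    out = np.empty(length + 1, np.uint8)
    i = 0
    tokens = rng.random(length)
    singles = _BASE_LOOKUP[rng.choice(4, size=length, p=[0.2, 0.3, 0.3, 0.2])]
    k = 0
    while i < length:
        if tokens[k] < cg_prob:
            out[i] = st.C
            out[i + 1] = st.G
            i += 2
        else:
            out[i] = singles[k]
            i += 1
        k += 1
    return out[:length]


def build_genome(config: SimConfig) -> GenomeModel:
    """Generate chromosomes, gene models and CGI annotation.

    Deterministic under ``truth_seed`` (falling back to ``seed``).
    """
    rng = _rng(1, config.effective_truth_seed)
    margin = 11_000  # room for upstream-10kb windows
    names = [f"chr{i + 1}" for i in range(config.n_autosomes)]
    chrom_class = {n: "autosome" for n in names}
    if config.x_present:
        names.append("chrX")
        chrom_class["chrX"] = "X"
    n_chrom = len(names)
    # tapered lengths (real karyotypes are unequal; this keeps chromosomal
    # rank statistics meaningful)
    lengths = {n: int(config.chrom_length * config.chrom_length_taper ** i)
               for i, n in enumerate(names)}

    seqs = {}
    for n in names:
        seq = _random_sequence(rng, lengths[n])
        # vertebrate genomes are CpG-depleted outside islands (the long-run
        # product of 5mC deamination): break a fraction of background CGs
        if config.background_cpg_depletion > 0:
            cg = st.cpg_starts(seq)
            hit = cg[rng.random(cg.size) < config.background_cpg_depletion]
            seq[hit] = st.T
        seqs[n] = seq

    # --- genes on a jittered grid so spans never overlap
    genes: list[GeneModel] = []
    total_len = sum(lengths.values())
    per_chrom = [int(round(config.n_genes * lengths[n] / total_len))
                 for n in names]
    gmin, gmax = config.gene_length
    for name, n_g in zip(names, per_chrom):
        if n_g == 0:
            continue
        L = lengths[name]
        usable = L - 2 * margin
        step = usable / n_g
        # inter-gene buffer keeps neighbouring promoters (and their CGIs)
        # out of each other's +/-2 kb metagene windows
        buffer = 2_800
        if step < gmax + buffer:
            raise SizingError(
                f"chromosome length {L} too short for {n_g} genes of up to {gmax} bp")
        for j in range(n_g):
            glen = int(rng.integers(gmin, gmax + 1))
            lo = margin + int(j * step)
            start = lo + int(rng.integers(0, max(1, int(step) - glen - buffer)))
            end = start + glen
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 5))
            cuts = np.sort(rng.choice(np.arange(start + 100, end - 100, 50),
                                      size=2 * (n_exons - 1), replace=False))
            bounds = [start, *cuts.tolist(), end]
            exons = [(bounds[2 * k], bounds[2 * k + 1]) for k in range(n_exons)]
            tss = start if strand == "+" else end - 1
            genes.append(GeneModel(f"{name}_g{j}", name, strand, tss, exons))

    # --- CGIs: a fraction anchored at gene TSS, the rest intergenic.
    # Both kinds are allocated per chromosome proportionally (stratified):
    # in a full-size genome per-chromosome feature composition is
    # essentially deterministic, and a faithful miniature must not inject
    # spurious chromosome-level composition noise.
    cgis: list[tuple[str, int, int]] = []
    cmin, cmax = config.cgi_length
    n_at_tss = min(int(round(config.n_cgis * config.cgi_at_tss_fraction)),
                   len(genes))
    genes_by_chrom: dict[str, list[GeneModel]] = {n: [] for n in names}
    for g in genes:
        genes_by_chrom[g.chromosome].append(g)
    for name in names:
        local = genes_by_chrom[name]
        n_c = min(len(local),
                  int(round(n_at_tss * len(local) / max(1, len(genes)))))
        for gi in rng.choice(len(local), size=n_c, replace=False):
            g = local[gi]
            clen = int(rng.integers(cmin, cmax + 1))
            s = max(0, g.tss_position - clen // 2)
            cgis.append((g.chromosome, s, min(lengths[g.chromosome], s + clen)))
    taken: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    for chrom, s, e in cgis:
        taken[chrom].append((s, e))
    n_left = config.n_cgis - len(cgis)
    total_len = sum(lengths.values())
    for ci, chrom in enumerate(names):
        n_c = int(round(n_left * lengths[chrom] / total_len))
        attempts = 0
        while n_c > 0:
            attempts += 1
            if attempts > 400 * config.n_cgis:
                raise SizingError("could not place requested CGIs without overlap")
            clen = int(rng.integers(cmin, cmax + 1))
            s = int(rng.integers(margin, lengths[chrom] - margin - clen))
            iv = (s, s + clen)
            near_tss = any(s - 2_000 < g.tss_position < s + clen + 2_000
                           for g in genes_by_chrom[chrom])
            overlap = any(not (iv[1] <= a or iv[0] >= b) for a, b in taken[chrom])
            if overlap or near_tss:
                continue
            taken[chrom].append(iv)
            cgis.append((chrom, *iv))
            n_c -= 1

    for chrom, s, e in cgis:
        seqs[chrom][s:e] = _cgi_sequence(rng, e - s, config.cgi_cpg_token_prob)

    genome = GenomeModel(
        chromosomes={n: seqs[n].tobytes().decode() for n in names},
        chrom_class=chrom_class, genes=genes,
        cgis=sorted(cgis), seed=config.effective_truth_seed)
    genome.validate()
    return genome


def assign_expression(genome: GenomeModel, config: SimConfig) -> pd.DataFrame:
    """Draw true FPKM values, plant the CpG->TpG promoter replacement, and
    assign ASE classes.

    For a configured fraction of low-expression genes (FPKM < 1), CpG
    dinucleotides in the TSS window are rewritten to TpG (or ApG for a
    smaller fraction) in the emitted sequence — the fixed sequence trace
    of 5-methylcytosine deamination. Returns a per-gene report of the
    edits. Mutates ``genome`` (sequences and gene fields) in place.
    """
    from .regions import tss_window  # local import to avoid a cycle

    rng = _rng(2, config.effective_truth_seed)
    genes = genome.genes
    n = len(genes)
    zero = rng.random(n) < config.fraction_zero_expression
    fpkm = np.where(zero, 0.0,
                    np.exp(rng.normal(config.fpkm_log_mean, config.fpkm_log_sd, n)))
    for g, f in zip(genes, fpkm):
        g.true_fpkm = float(f)

    arrs = {c: bytearray(s, "ascii") for c, s in genome.chromosomes.items()}
    # stratified by chromosome so the miniature genome keeps per-chromosome
    # promoter composition balanced (see build_genome)
    replaced: set[int] = set()
    for chrom in genome.chromosomes:
        low = np.array([i for i, g in enumerate(genes)
                        if g.chromosome == chrom and fpkm[i] < 1.0])
        n_replace = int(round(
            low.size * config.fraction_low_expression_with_tpg_replacement))
        if n_replace:
            replaced |= set(rng.choice(low, size=n_replace, replace=False).tolist())
    rows = []
    for i, g in enumerate(genes):
        s, e = tss_window(g.tss_position, g.strand)
        L = len(arrs[g.chromosome])
        if s < 0 or e > L:
            warnings.warn(f"TSS window of {g.id} extends beyond chromosome; skipped")
            rows.append({"gene": g.id, "fpkm": g.true_fpkm, "replaced": False,
                         "n_to_tpg": 0, "n_to_apg": 0})
            continue
        n_tpg = n_apg = 0
        if i in replaced:
            arr = arrs[g.chromosome]
            window = st.seq_array(bytes(arr[s:e]))
            for p in st.cpg_starts(window):
                r = rng.random()
                if r < config.tpg_replace_prob:
                    arr[s + p] = st.T
                    n_tpg += 1
                elif r < config.tpg_replace_prob + config.apg_replace_prob:
                    arr[s + p] = st.A
                    n_apg += 1
        rows.append({"gene": g.id, "fpkm": g.true_fpkm, "replaced": i in replaced,
                     "n_to_tpg": n_tpg, "n_to_apg": n_apg})
    genome.chromosomes = {c: a.decode() for c, a in arrs.items()}

    expressed = [i for i, g in enumerate(genes) if g.true_fpkm >= 1.0]
    n_ase = config.n_ase_genes + config.n_monoallelic_genes
    if n_ase > len(expressed):
        raise SizingError("not enough expressed genes for the requested ASE classes")
    picked = rng.choice(expressed, size=n_ase, replace=False)
    for k, gi in enumerate(picked):
        g = genes[gi]
        if k < config.n_ase_genes:
            g.ase_class = "ase"
            high_alt = rng.random() < 0.5
            g.ase_alt_prob = config.ase_imbalance if high_alt else 1 - config.ase_imbalance
        else:
            g.ase_class = "monoallelic"
            g.ase_alt_prob = 1.0 if rng.random() < 0.5 else 0.0
    return pd.DataFrame(rows)


def plant_variants(genome: GenomeModel, config: SimConfig) -> pd.DataFrame:
    """Place heterozygous SNPs: C->T enriched at CpG sites, CpG-creating
    variants, scattered non-CpG SNPs, and exonic SNPs for ASE testing.

    Returns the variant truth table (chrom, pos, ref, alt, destroys_cpg,
    creates_cpg, gene) and fills ``het_snps`` of the genes selected for
    allelic analysis.
    """
    rng = _rng(3, config.effective_truth_seed)
    rows = []
    used: dict[str, set[int]] = {c: set() for c in genome.chromosomes}

    def add(chrom, pos, ref, alt, destroys=False, creates=False, gene=""):
        if pos in used[chrom]:
            return False
        used[chrom].add(pos)
        rows.append({"chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt,
                     "destroys_cpg": destroys, "creates_cpg": creates,
                     "gene": gene})
        return True

    for chrom, seq in genome.chromosomes.items():
        arr = st.seq_array(seq)
        cpg = st.cpg_starts(arr)
        n_pick = int(round(cpg.size * config.cpg_snp_fraction))
        if n_pick > cpg.size:
            raise SizingError("cpg_snp_fraction exceeds available CpG sites")
        for p in rng.choice(cpg, size=n_pick, replace=False):
            if rng.random() < 0.5:
                add(chrom, p, "C", "T", destroys=True)
            else:
                add(chrom, p + 1, "G", "A", destroys=True)

        # CpG-creating variants: mutate the base after a C to G
        eligible = np.where((arr[:-1] == st.C) &
                            ((arr[1:] == st.A) | (arr[1:] == st.T)))[0]
        n_creates = min(config.creates_cpg_count // len(genome.chromosomes) + 1,
                        eligible.size)
        for p in rng.choice(eligible, size=n_creates, replace=False):
            ref = chr(arr[p + 1])
            add(chrom, p + 1, ref, "G", creates=True)

        noncpg_c = np.where(arr == st.C)[0]
        noncpg_c = np.setdiff1d(noncpg_c, cpg, assume_unique=False)
        n_pick = int(round(noncpg_c.size * config.noncpg_snp_fraction))
        for p in rng.choice(noncpg_c, size=n_pick, replace=False):
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == "C":
                alt = "T"
            add(chrom, p, "C", alt)

    # exonic het SNPs for genes entering the allelic analysis
    candidates = [g for g in genome.genes
                  if g.ase_class == "none" and g.true_fpkm >= 1.0]
    n_extra = min(config.n_nonase_het_genes, len(candidates))
    extra = list(rng.choice(len(candidates), size=n_extra, replace=False))
    targets = [g for g in genome.genes if g.ase_class != "none"]
    targets += [candidates[i] for i in extra]
    for g in targets:
        arr = st.seq_array(genome.chromosomes[g.chromosome])
        placed = 0
        exon_pos = np.concatenate([np.arange(s, e) for s, e in g.exons])
        rng.shuffle(exon_pos)
        for p in exon_pos:
            if placed >= config.snps_per_ase_gene:
                break
            if any(abs(p - q) <= 25 for q in used[g.chromosome]
                   if abs(p - q) <= 25):
                continue
            ref = chr(arr[p])
            if ref not in BASES:
                continue
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            if add(g.chromosome, p, ref, alt, gene=g.id):
                g.het_snps.append((int(p), ref, alt))
                placed += 1

    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                     "destroys_cpg", "creates_cpg", "gene"])
    return df.sort_values(["chrom", "pos"], ignore_index=True)


@dataclass
class ChromTruth:
    plus_pos: np.ndarray
    plus_ctx: np.ndarray
    plus_p: np.ndarray
    minus_pos: np.ndarray
    minus_ctx: np.ndarray
    minus_p: np.ndarray
    effect_pos: np.ndarray      # plus-strand CpG starts with tissue effects
    effect_p: np.ndarray        # (n_effect, n_tissues) absolute per-tissue p


@dataclass
class MethylomeTruth:
    """Planted per-cytosine methylation probabilities.

    ``p`` is stored per strand; CpG probabilities are strand-symmetric by
    construction. Tissue-variable sites (a sparse subset of CpGs,
    emulating tissue-specific differentially methylated sites) carry an
    absolute per-tissue probability that overrides the base value.
    """

    tissues: tuple[str, ...]
    chroms: dict[str, ChromTruth]

    def _tissue_index(self, tissue: str | None) -> int | None:
        if tissue is None:
            return None
        return self.tissues.index(tissue)

    def full_arrays(self, chrom: str, chrom_length: int,
                    tissue: str | None = None):
        """Per-position probability arrays (NaN away from cytosines)."""
        ct = self.chroms[chrom]
        plus = np.full(chrom_length, np.nan, np.float64)
        minus = np.full(chrom_length, np.nan, np.float64)
        plus[ct.plus_pos] = ct.plus_p
        minus[ct.minus_pos] = ct.minus_p
        ti = self._tissue_index(tissue)
        if ti is not None and ct.effect_pos.size:
            p_t = ct.effect_p[:, ti]
            plus[ct.effect_pos] = p_t
            partner = ct.effect_pos + 1
            ok = partner < chrom_length
            minus[partner[ok]] = p_t[ok]
        return plus, minus

    def to_frame(self, tissue: str | None = None) -> pd.DataFrame:
        rows = []
        for chrom, ct in self.chroms.items():
            for strand, pos, ctx, p in (("+", ct.plus_pos, ct.plus_ctx, ct.plus_p),
                                        ("-", ct.minus_pos, ct.minus_ctx, ct.minus_p)):
                p = p.copy()
                ti = self._tissue_index(tissue)
                if ti is not None and ct.effect_pos.size:
                    eff = ct.effect_pos if strand == "+" else ct.effect_pos + 1
                    idx = np.searchsorted(pos, eff)
                    ok = (idx < pos.size) & (pos[np.minimum(idx, pos.size - 1)] == eff)
                    p[idx[ok]] = ct.effect_p[ok, ti]
                rows.append(pd.DataFrame({
                    "chrom": chrom, "pos": pos, "strand": strand,
                    "context": pd.Categorical.from_codes(
                        ctx, categories=list(st.CONTEXT_LABELS)),
                    "p_true": p}))
        return pd.concat(rows, ignore_index=True)

    def cpg_truth(self, tissue: str | None = None) -> pd.DataFrame:
        """Combined-CpG truth keyed at the plus-strand C position."""
        rows = []
        for chrom, ct in self.chroms.items():
            mask = ct.plus_ctx == st.CPG
            pos = ct.plus_pos[mask]
            p = ct.plus_p[mask].copy()
            ti = self._tissue_index(tissue)
            if ti is not None and ct.effect_pos.size:
                idx = np.searchsorted(pos, ct.effect_pos)
                ok = (idx < pos.size) & (pos[np.minimum(idx, pos.size - 1)]
                                         == ct.effect_pos)
                p[idx[ok]] = ct.effect_p[ok, ti]
            rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "p_true": p}))
        return pd.concat(rows, ignore_index=True)

    def n_sites(self) -> int:
        return sum(ct.plus_pos.size + ct.minus_pos.size
                   for ct in self.chroms.values())


def _beta(rng, mean, conc):
    mean = np.clip(mean, 1e-4, 1 - 1e-4)
    return rng.beta(mean * conc, (1 - mean) * conc)


def _beta_array(rng, mean: float, conc: float, shape) -> np.ndarray:
    mean = min(max(mean, 1e-4), 1 - 1e-4)
    return rng.beta(mean * conc, (1 - mean) * conc, shape)


def plant_methylome(genome: GenomeModel, config: SimConfig) -> MethylomeTruth:
    """Draw the planted methylation probability of every cytosine.

    CpG probabilities come from a two-component mixture: a low component
    for CGI and TSS-window cytosines and a high component (~0.8)
    elsewhere, with the TSS dip V-shaped (deepest at the TSS) and its
    depth anticoupled to expression. Gene-body high-component means rise
    weakly with expression. Non-CpG cytosines get small Beta-distributed
    probabilities with CHG above CHH. On a female X, CpG probabilities are
    shifted toward an inactivation mixture (halfway to 0.85).
    """
    rng = _rng(4, config.effective_truth_seed)
    n_t = len(config.tissues)
    chroms: dict[str, ChromTruth] = {}
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genome.genes:
        genes_by_chrom.setdefault(g.chromosome, []).append(g)

    for chrom, seq in genome.chromosomes.items():
        arr = st.seq_array(seq)
        L = arr.size
        plus_pos, plus_ctx, minus_pos, minus_ctx = st.cytosine_contexts(arr)

        cgi_mask = np.zeros(L, bool)
        for c, s, e in genome.cgis:
            if c == chrom:
                cgi_mask[s:e] = True
        tss_mean = np.full(L, np.nan)
        body_mean = np.full(L, np.nan)
        for g in genes_by_chrom.get(chrom, []):
            gs, ge = g.span
            mh = 0.68 + 0.14 * (g.true_fpkm / (g.true_fpkm + 5.0))
            cut = int((ge - gs) * 0.05)
            bs, be = (gs + cut, ge) if g.strand == "+" else (gs, ge - cut)
            body_mean[bs:be] = mh
            # V-shaped hypomethylation dip centred on the TSS, deepest for
            # highly expressed genes; wider than any promoter CGI so the
            # profile minimum sits at the anchor
            hw = config.tss_dip_halfwidth
            s, e = max(0, g.tss_position - hw), min(L, g.tss_position + hw)
            m_low = 0.05 + 0.60 * np.exp(-g.true_fpkm)
            off = np.abs(np.arange(s, e) - g.tss_position) / hw
            # convex ramp: the promoter stays uniformly low and rises
            # sharply near its edge (island-edge transition), so levels
            # stay bimodal while the profile minimum sits at the anchor
            tss_mean[s:e] = m_low + 0.18 * off + (0.57 - m_low) * off ** 3

        # CpG probabilities, assigned at plus-strand CpG starts
        is_cpg = plus_ctx == st.CPG
        cpg_pos = plus_pos[is_cpg]
        p_cpg = np.empty(cpg_pos.size)
        in_tss = ~np.isnan(tss_mean[cpg_pos])
        in_cgi = cgi_mask[cpg_pos] & ~in_tss
        in_body = ~np.isnan(body_mean[cpg_pos]) & ~in_tss & ~in_cgi
        other = ~(in_tss | in_cgi | in_body)

        p_cpg[in_tss] = _beta(rng, tss_mean[cpg_pos[in_tss]], 15.0)
        low = rng.random(int(in_cgi.sum())) < 0.95
        p_cgi = np.where(low, rng.beta(0.5, 10.0, low.size),
                         rng.beta(20.0, 5.0, low.size))
        p_cpg[in_cgi] = p_cgi
        hi = rng.random(int(in_body.sum())) < 0.9
        p_body = np.where(hi, _beta(rng, body_mean[cpg_pos[in_body]], 25.0),
                          rng.beta(0.5, 10.0, hi.size))
        p_cpg[in_body] = p_body
        hi = rng.random(int(other.sum())) < 0.9
        p_other = np.where(hi, rng.beta(20.0, 5.0, hi.size),
                           rng.beta(0.5, 10.0, hi.size))
        p_cpg[other] = p_other

        if genome.chrom_class.get(chrom) == "X" and config.sex == "female":
            # inactive-X methylation: shift toward the inactivation mixture
            p_cpg = 0.5 * p_cpg + 0.5 * 0.85

        pfull = np.zeros(L)
        pfull[cpg_pos] = p_cpg

        plus_p = np.empty(plus_pos.size)
        plus_p[is_cpg] = p_cpg
        # non-CpG bulk: small Beta-distributed probabilities
        for code, mean in ((st.CHG, config.chg_meth_mean),
                           (st.CHH, config.chh_meth_mean)):
            m = plus_ctx == code
            if mean > 0:
                plus_p[m] = rng.beta(0.5, 0.5 * (1 - mean) / mean, int(m.sum()))
            else:
                plus_p[m] = 0.0
        m = plus_ctx == st.UNKNOWN
        plus_p[m] = 0.0

        minus_p = np.empty(minus_pos.size)
        m_cpg = minus_ctx == st.CPG
        minus_p[m_cpg] = pfull[minus_pos[m_cpg] - 1]  # strand symmetry
        for code, mean in ((st.CHG, config.chg_meth_mean),
                           (st.CHH, config.chh_meth_mean)):
            m = minus_ctx == code
            if mean > 0:
                minus_p[m] = rng.beta(0.5, 0.5 * (1 - mean) / mean, int(m.sum()))
            else:
                minus_p[m] = 0.0
        minus_p[minus_ctx == st.UNKNOWN] = 0.0

        # tissue-variable sites: switch-like low/high state per tissue
        n_eff = int(round(cpg_pos.size * config.tissue_variable_fraction))
        if n_eff > 0:
            eff_pos = np.sort(rng.choice(cpg_pos, size=n_eff, replace=False))
            high = rng.random((n_eff, n_t)) < 0.5
            p_lo = _beta_array(rng, config.tissue_effect_low, 15.0, (n_eff, n_t))
            p_hi = _beta_array(rng, config.tissue_effect_high, 15.0, (n_eff, n_t))
            eff_p = np.where(high, p_hi, p_lo)
            if genome.chrom_class.get(chrom) == "X" and config.sex == "female":
                eff_p = 0.5 * eff_p + 0.5 * 0.85
        else:
            eff_pos = np.empty(0, np.int64)
            eff_p = np.empty((0, n_t))
        chroms[chrom] = ChromTruth(plus_pos, plus_ctx, plus_p,
                                   minus_pos, minus_ctx, minus_p,
                                   eff_pos, eff_p)
    return MethylomeTruth(tuple(config.tissues), chroms)


@dataclass
class SimulatedData:
    """Everything one simulated individual produces, plus its truth."""

    config: SimConfig
    genome: GenomeModel
    truth: MethylomeTruth
    variants: pd.DataFrame
    reduced: ReducedGenome
    reads: dict[str, list[tuple[str, bytes]]]
    placements: pd.DataFrame
    control_pileups: PileupTable
    wgs_pileups: PileupTable
    allelic_counts: pd.DataFrame
    expression: pd.DataFrame


def _ref_index(arr: np.ndarray) -> np.ndarray:
    idx = np.full(arr.size, -1, np.int8)
    for i, b in enumerate(BASES):
        idx[arr == ord(b)] = i
    return idx


def _pileup_for(rng, arr: np.ndarray, depth: np.ndarray,
                snps: list[tuple[int, str]], config: SimConfig) -> ChromPileup:
    """Assemble base counts / MAPQ for one chromosome given a depth vector."""
    L = arr.size
    counts = np.zeros((4, L), np.int32)
    ref_idx = _ref_index(arr)
    covered = np.where((depth > 0) & (ref_idx >= 0))[0]
    counts[ref_idx[covered], covered] = depth[covered]
    # scattered base-call errors
    if config.pileup_error_rate > 0 and covered.size:
        err = rng.binomial(depth[covered], config.pileup_error_rate)
        nz = err > 0
        if nz.any():
            pos = covered[nz]
            eb = rng.integers(0, 4, pos.size)
            ok = eb != ref_idx[pos]
            pos, eb, e = pos[ok], eb[ok], err[nz][ok]
            np.subtract.at(counts, (ref_idx[pos], pos), e)
            np.add.at(counts, (eb, pos), e)
    for pos, alt in snps:
        d = int(depth[pos])
        if d <= 0 or ref_idx[pos] < 0:
            continue
        a = int(rng.binomial(d, 0.5))
        counts[ref_idx[pos], pos] -= a
        counts[BASES.index(alt), pos] += a
    mapq = (42.0 + rng.normal(0.0, 2.0, L)).astype(np.float32)
    low = rng.random(L) < config.low_mapq_fraction
    mapq[low] = rng.uniform(0.0, 20.0, int(low.sum()))
    return ChromPileup(counts, mapq)


def simulate_reads(genome: GenomeModel, truth: MethylomeTruth,
                   variants: pd.DataFrame, config: SimConfig) -> SimulatedData:
    """Simulate RRBS reads, control/WGS pileups, allelic counts and the
    expression table from the planted truth.

    Each RRBS read spans one strand of one size-selected MspI fragment;
    a cytosine is emitted as C with probability p + (1-p)(1-conversion)
    and as T otherwise (mirrored to G/A for minus-strand cytosines).
    Reads from a heterozygous fragment are drawn from a random haplotype,
    so SNP alleles show through. WGS pileup depth carries a GC-bias
    penalty exp(-k * CpG count of the surrounding 100 bp), which starves
    CpG-rich windows of SNP-calling depth; the targeted control (the same
    MspI library without bisulfite) does not.
    """
    rng = _rng(5, config.seed)
    reduced = build_reduced_genome(genome, *config.library_insert_range)
    if len(reduced) == 0:
        raise SizingError("no retained fragments in the library size range")
    conv = config.conversion_rate

    var_by_chrom: dict[str, list[tuple[int, str]]] = {c: [] for c in genome.chromosomes}
    for _, v in variants.iterrows():
        var_by_chrom[v["chrom"]].append((int(v["pos"]), v["alt"]))
    frag_snps = []
    for frag in reduced.fragments:
        frag_snps.append([(p - frag.start, alt)
                          for p, alt in var_by_chrom[frag.chromosome]
                          if frag.start <= p < frag.end])

    frag_cache = []
    for i, frag in enumerate(reduced.fragments):
        arr = st.seq_array(reduced.sequences[i])
        frag_cache.append((arr, np.where(arr == st.C)[0], np.where(arr == st.G)[0]))

    chrom_lengths = genome.chrom_lengths()
    reads: dict[str, list[tuple[str, bytes]]] = {}
    placement_rows = {"read_id": [], "tissue": [], "frag_index": [], "strand": []}

    for tissue in config.tissues:
        tissue_reads: list[tuple[str, bytes]] = []
        full = {c: truth.full_arrays(c, chrom_lengths[c], tissue)
                for c in genome.chromosomes}
        for i, frag in enumerate(reduced.fragments):
            n = int(rng.poisson(config.rrbs_depth_target))
            if n == 0:
                continue
            arr, cpos, gpos = frag_cache[i]
            L = arr.size
            p_plus_full, p_minus_full = full[frag.chromosome]
            n_plus = int(rng.binomial(n, 0.5))
            counter = 0
            for strand, n_rows in (("+", n_plus), ("-", n - n_plus)):
                if n_rows == 0:
                    continue
                block = np.tile(arr, (n_rows, 1))
                if strand == "+":
                    p = p_plus_full[frag.start + cpos]
                    prob = p + (1.0 - p) * (1.0 - conv)
                    draw = rng.random((n_rows, cpos.size)) < prob
                    block[:, cpos] = np.where(draw, st.C, st.T)
                else:
                    p = p_minus_full[frag.start + gpos]
                    prob = p + (1.0 - p) * (1.0 - conv)
                    draw = rng.random((n_rows, gpos.size)) < prob
                    block[:, gpos] = np.where(draw, st.G, st.A)
                if frag_snps[i]:
                    hap_alt = rng.random(n_rows) < 0.5
                    for lp, alt in frag_snps[i]:
                        ab = ord(alt)
                        if strand == "+" and alt == "C":
                            basecall = np.where(rng.random(n_rows) < 1 - conv,
                                                st.C, st.T)
                        elif strand == "-" and alt == "G":
                            basecall = np.where(rng.random(n_rows) < 1 - conv,
                                                st.G, st.A)
                        else:
                            basecall = np.full(n_rows, ab, np.uint8)
                        block[hap_alt, lp] = basecall[hap_alt]
                if config.sequencing_error > 0:
                    flip = rng.random(block.shape) < config.sequencing_error
                    noise = _BASE_LOOKUP[rng.integers(0, 4, block.shape)]
                    block = np.where(flip, noise, block)
                raw = block.tobytes()
                for r in range(n_rows):
                    rid = f"{tissue}:f{i}:r{counter}"
                    counter += 1
                    seq = raw[r * L:(r + 1) * L]
                    if strand == "-":
                        seq = st.revcomp(seq)
                    tissue_reads.append((rid, seq))
                    placement_rows["read_id"].append(rid)
                    placement_rows["tissue"].append(tissue)
                    placement_rows["frag_index"].append(i)
                    placement_rows["strand"].append(strand)
        reads[tissue] = tissue_reads
    placements = pd.DataFrame(placement_rows)

    # --- pileups
    control = PileupTable()
    wgs = PileupTable()
    for chrom, seq in genome.chromosomes.items():
        arr = st.seq_array(seq)
        L = arr.size
        depth_c = np.zeros(L, np.int64)
        for i, frag in enumerate(reduced.fragments):
            if frag.chromosome == chrom:
                depth_c[frag.start:frag.end] = rng.poisson(
                    config.control_mean_coverage, frag.length)
        control.chroms[chrom] = _pileup_for(rng, arr, depth_c,
                                            var_by_chrom[chrom], config)
        ind = np.zeros(L)
        ind[st.cpg_starts(arr)] = 1.0
        win = np.convolve(ind, np.ones(101), mode="same")
        lam = config.wgs_mean_coverage * np.exp(-config.gc_bias_k * win)
        depth_w = rng.poisson(lam)
        wgs.chroms[chrom] = _pileup_for(rng, arr, depth_w,
                                        var_by_chrom[chrom], config)

    # --- expression table (true FPKM + multiplicative log-normal noise)
    expr_rows = []
    for tissue in config.tissues:
        noise = np.exp(rng.normal(0.0, config.fpkm_noise_sigma, len(genome.genes)))
        for g, nz in zip(genome.genes, noise):
            expr_rows.append({"gene": g.id, "tissue": tissue,
                              "fpkm": g.true_fpkm * nz})
    expression = pd.DataFrame(expr_rows)
    expr_lookup = expression.set_index(["gene", "tissue"])["fpkm"]

    # --- allelic RNA counts at exonic het SNPs
    ase_rows = []
    for g in genome.genes:
        if not g.het_snps:
            continue
        for tissue in config.tissues:
            fpkm_t = float(expr_lookup.loc[(g.id, tissue)])
            lam = config.ase_rna_depth if fpkm_t >= 0.1 else 1.0
            for pos, ref, alt in g.het_snps:
                d_rna = int(rng.poisson(lam))
                n_alt = int(rng.binomial(d_rna, g.ase_alt_prob)) if d_rna else 0
                d_dna = int(rng.poisson(config.wgs_mean_coverage))
                dna_alt = int(rng.binomial(d_dna, 0.5)) if d_dna else 0
                ase_rows.append({
                    "gene": g.id, "tissue": tissue, "chrom": g.chromosome,
                    "pos": pos, "ref": ref, "alt": alt,
                    "rna_ref": d_rna - n_alt, "rna_alt": n_alt,
                    "dna_ref": d_dna - dna_alt, "dna_alt": dna_alt,
                })
    allelic = pd.DataFrame(ase_rows)

    return SimulatedData(config, genome, truth, variants, reduced, reads,
                         placements, control, wgs, allelic, expression)


def simulate_dataset(config: SimConfig) -> SimulatedData:
    """Run the whole generator: genome, expression + promoter edits,
    variants, methylome, then sequencing data."""
    genome = build_genome(config)
    assign_expression(genome, config)
    variants = plant_variants(genome, config)
    truth = plant_methylome(genome, config)
    return simulate_reads(genome, truth, variants, config)
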