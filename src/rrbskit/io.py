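"""Readers and writers for the package's text formats.

Conventions: internal coordinates are 0-based, half-open; positions are
written 1-based in VCF-like and CGmap-style files and 0-based half-open
in BED. All writers round-trip through the readers in this module.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .snpfilter import PileupTable
from .synthgenome import GeneModel


def write_fasta(path, chromosomes: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in chromosomes.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path, reads: Iterable[tuple[str, bytes]], quality: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            s = seq.decode() if isinstance(seq, bytes) else seq
            fh.write(f"@{rid}\n{s}\n+\n{quality * len(s)}\n")


def read_fastq(path) -> list[tuple[str, bytes]]:
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((header[1:].strip(), seq.encode()))
    return out


def write_genes_tsv(path, genes: Iterable[GeneModel]) -> None:
    rows = []
    for g in genes:
        rows.append({
            "gene": g.id, "chrom": g.chromosome, "strand": g.strand,
            "tss": g.tss_position,
            "exons": ",".join(f"{s}-{e}" for s, e in g.exons),
            "true_fpkm": g.true_fpkm, "ase_class": g.ase_class,
            "het_snps": ",".join(f"{p}:{r}:{a}" for p, r, a in g.het_snps),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genes_tsv(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    genes = []
    for _, r in df.iterrows():
        exons = [tuple(map(int, x.split("-"))) for x in str(r["exons"]).split(",")]
        snps = []
        if r["het_snps"]:
            for item in str(r["het_snps"]).split(","):
                p, ref, alt = item.split(":")
                snps.append((int(p), ref, alt))
        genes.append(GeneModel(r["gene"], r["chrom"], r["strand"], int(r["tss"]),
                               exons, float(r["true_fpkm"]), r["ase_class"],
                               het_snps=snps))
    return genes


def write_bed(path, intervals: Iterable[tuple]) -> None:
    """Intervals as (chrom, start, end[, name[, score[, strand]]])."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[:df.shape[1]]
    return df


def write_cgmap(path, table: pd.DataFrame) -> None:
    """Methylation table as CGmap-style TSV (1-based positions)."""
    out = table.copy()
    out["pos"] = out["pos"] + 1
    cols = ["chrom", "context", "pos", "strand", "level", "meth", "total"]
    out[cols].to_csv(path, sep="\t", index=False)


def read_cgmap(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"] - 1
    return df[["chrom", "pos", "strand", "context", "meth", "total", "level"]]


VCF_HEADER = ("##fileformat=VCFv4.2\n"
              '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
              '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
              '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mean MAPQ">\n'
              "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")

_GT = {"het": "0/1", "hom_alt": "1/1", "hom_ref": "0/0"}
_GT_INV = {v: k for k, v in _GT.items()}


def write_vcf(path, variants: pd.DataFrame) -> None:
    """Minimal VCF: CHROM, 1-based POS, REF, ALT, GT, DP, MQ."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for _, v in variants.iterrows():
            gt = _GT.get(v.get("genotype", "het"), "0/1")
            fh.write(f"{v['chrom']}\t{v['pos'] + 1}\t.\t{v['ref']}\t{v['alt']}"
                     f"\t.\tPASS\tDP={int(v['depth'])};MQ={v['mapq']:.2f}"
                     f"\tGT\t{gt}\n")


def read_vcf(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            info = dict(kv.split("=") for kv in f[7].split(";"))
            rows.append({"chrom": f[0], "pos": int(f[1]) - 1, "ref": f[3],
                         "alt": f[4], "genotype": _GT_INV.get(f[9], "het"),
                         "depth": int(info["DP"]), "mapq": float(info["MQ"])})
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "genotype", "depth", "mapq"])


def write_pileups(path, pileups: PileupTable, chromosomes: Mapping[str, str]) -> None:
    pileups.to_frame(chromosomes).to_csv(path, sep="\t", index=False)


def read_pileups(path, chrom_lengths: Mapping[str, int]) -> PileupTable:
    return PileupTable.from_frame(pd.read_csv(path, sep="\t"), chrom_lengths)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def export_dataset(sim, out_dir) -> None:
    """Write a simulated dataset to a directory of plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "genome.fa", sim.genome.chromosomes)
    write_genes_tsv(out / "genes.tsv", sim.genome.genes)
    write_bed(out / "cgis.bed", [(c, s, e, f"cgi_{i}")
                                 for i, (c, s, e) in enumerate(sim.genome.cgis)])
    write_table(out / "variant_truth.tsv", sim.variants)
    write_table(out / "methylome_truth.tsv", sim.truth.to_frame())
    for tissue, reads in sim.reads.items():
        write_fastq(out / f"rrbs_{tissue}.fastq", reads)
    write_pileups(out / "control_pileups.tsv", sim.control_pileups,
                  sim.genome.chromosomes)
    write_pileups(out / "wgs_pileups.tsv", sim.wgs_pileups,
                  sim.genome.chromosomes)
    write_table(out / "expression.tsv", sim.expression)
    write_table(out / "allelic_counts.tsv", sim.allelic_counts)
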