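"""The synthetic genome/methylome generator and read simulator."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rrbskit._seqtools as st
from rrbskit.errors import SizingError
from rrbskit.synthgenome import (GeneModel, GenomeModel, SimConfig,
                                 assign_expression, build_genome,
                                 plant_methylome, plant_variants,
                                 simulate_dataset, simulate_reads)
from tests.conftest import SMALL_CONFIG

TINY = dict(tissues=("liver", "muscle"), chrom_length=120_000, n_genes=24,
            n_cgis=14, n_ase_genes=3, n_monoallelic_genes=1,
            n_nonase_het_genes=4)


class TestBuildGenome:
    def test_deterministic_under_seed(self):
        g1 = build_genome(SimConfig(seed=1, **TINY))
        g2 = build_genome(SimConfig(seed=1, **TINY))
        assert g1.chromosomes == g2.chromosomes
        assert [x.exons for x in g1.genes] == [x.exons for x in g2.genes]
        assert g1.cgis == g2.cgis

    def test_different_seeds_differ(self):
        g1 = build_genome(SimConfig(seed=1, **TINY))
        g2 = build_genome(SimConfig(seed=2, **TINY))
        assert g1.chromosomes != g2.chromosomes

    def test_no_cgis_no_peaks(self):
        cfg = dict(TINY)
        cfg["n_cgis"] = 0
        g = build_genome(SimConfig(seed=1, **cfg))
        assert g.cgis == []

    def test_cgi_cpg_density_elevated(self):
        g = build_genome(SimConfig(seed=1, **TINY))
        inside = outside_len = 0
        inside_len = outside = 0
        for chrom, seq in g.chromosomes.items():
            arr = st.seq_array(seq)
            mask = np.zeros(arr.size, bool)
            for c, s, e in g.cgis:
                if c == chrom:
                    mask[s:e] = True
            starts = st.cpg_starts(arr)
            inside += int(mask[starts].sum())
            outside += int((~mask[starts]).sum())
            inside_len += int(mask.sum())
            outside_len += int((~mask).sum())
        density_in = 100 * inside / inside_len
        density_out = 100 * outside / outside_len
        assert density_in >= 3 * density_out

    def test_structure_invariants(self):
        g = build_genome(SimConfig(seed=5, **TINY))
        g.validate()  # exercises gene/CGI/X-count invariants
        assert sum(1 for c in g.chrom_class.values() if c == "X") == 1

    def test_sizing_error(self):
        cfg = dict(TINY)
        cfg["chrom_length"] = 40_000
        with pytest.raises(SizingError):
            build_genome(SimConfig(seed=1, **cfg))


class TestAssignExpression:
    def test_replacement_conserves_dinucleotides(self):
        cfg = SimConfig(seed=2, **TINY)
        g = build_genome(cfg)
        before = {c: (st.cpg_starts(st.seq_array(s)).size,
                      st.dinuc_starts(st.seq_array(s), "TG").size,
                      st.dinuc_starts(st.seq_array(s), "AG").size)
                  for c, s in g.chromosomes.items()}
        report = assign_expression(g, cfg)
        after = {c: (st.cpg_starts(st.seq_array(s)).size,
                     st.dinuc_starts(st.seq_array(s), "TG").size,
                     st.dinuc_starts(st.seq_array(s), "AG").size)
                 for c, s in g.chromosomes.items()}
        n_tpg = report["n_to_tpg"].sum()
        n_apg = report["n_to_apg"].sum()
        assert n_tpg > 0
        total_before = np.array([before[c] for c in before]).sum(axis=0)
        total_after = np.array([after[c] for c in after]).sum(axis=0)
        assert total_before[0] - total_after[0] == n_tpg + n_apg
        # every CpG rewritten to TpG adds exactly one TpG (likewise ApG)
        assert total_after[1] - total_before[1] == n_tpg
        assert total_after[2] - total_before[2] == n_apg

    def test_replacement_targets_low_expression(self):
        cfg = SimConfig(seed=2, **TINY)
        g = build_genome(cfg)
        report = assign_expression(g, cfg)
        assert (report.loc[report["replaced"], "fpkm"] < 1.0).all()

    def test_zero_replacement_fraction(self):
        cfg = SimConfig(seed=2, fraction_low_expression_with_tpg_replacement=0.0,
                        **TINY)
        g = build_genome(cfg)
        report = assign_expression(g, cfg)
        assert report["n_to_tpg"].sum() == 0


class TestPlantVariants:
    def setup_planted(self, seed=3):
        cfg = SimConfig(seed=seed, **TINY)
        g = build_genome(cfg)
        assign_expression(g, cfg)
        return g, plant_variants(g, cfg), cfg

    def test_ref_matches_genome_and_alt_differs(self):
        g, var, _ = self.setup_planted()
        for _, v in var.sample(50, random_state=0).iterrows():
            assert g.chromosomes[v["chrom"]][v["pos"]] == v["ref"]
            assert v["alt"] != v["ref"]

    def test_destroying_flags(self):
        g, var, _ = self.setup_planted()
        destroyed = var[var["destroys_cpg"]]
        assert len(destroyed) > 0
        for _, v in destroyed.iterrows():
            seq = g.chromosomes[v["chrom"]]
            if v["ref"] == "C":
                assert seq[v["pos"]:v["pos"] + 2] == "CG"
            else:
                assert seq[v["pos"] - 1:v["pos"] + 1] == "CG"

    def test_creating_flags(self):
        g, var, _ = self.setup_planted()
        created = var[var["creates_cpg"]]
        assert len(created) > 0
        for _, v in created.iterrows():
            assert v["alt"] == "G"
            assert g.chromosomes[v["chrom"]][v["pos"] - 1] == "C"

    def test_planted_count_within_binomial_interval(self):
        g, var, cfg = self.setup_planted()
        n_cpg = sum(st.cpg_starts(st.seq_array(s)).size
                    for s in g.chromosomes.values())
        expected = n_cpg * cfg.cpg_snp_fraction
        lo, hi = stats.binom.interval(0.99, n_cpg, cfg.cpg_snp_fraction)
        assert lo <= var["destroys_cpg"].sum() <= hi
        assert expected > 0

    def test_ase_genes_have_het_snps(self):
        g, _, _ = self.setup_planted()
        for gene in g.genes:
            if gene.ase_class != "none":
                assert len(gene.het_snps) >= 1
                span = gene.span
                for p, ref, alt in gene.het_snps:
                    assert span[0] <= p < span[1]
                    assert g.chromosomes[gene.chromosome][p] == ref


@pytest.fixture(scope="module")
def planted():
    cfg = SimConfig(seed=4, **TINY)
    g = build_genome(cfg)
    assign_expression(g, cfg)
    plant_variants(g, cfg)
    return g, plant_methylome(g, cfg), cfg


class TestPlantMethylome:

    def test_conservation_every_cytosine_once(self, planted):
        g, truth, _ = planted
        n_c = sum(int((st.seq_array(s) == st.C).sum())
                  + int((st.seq_array(s) == st.G).sum())
                  for s in g.chromosomes.values())
        assert truth.n_sites() == n_c

    def test_probabilities_in_unit_interval(self, planted):
        _, truth, _ = planted
        tf = truth.to_frame()
        assert tf["p_true"].between(0, 1).all()

    def test_noncpg_low_with_chg_above_chh(self, planted):
        _, truth, _ = planted
        tf = truth.to_frame()
        noncpg = tf[tf["context"].isin(["CHG", "CHH"])]
        assert noncpg["p_true"].mean() < 0.01
        chg = tf.loc[tf["context"] == "CHG", "p_true"].mean()
        chh = tf.loc[tf["context"] == "CHH", "p_true"].mean()
        assert chg > chh

    def test_cpg_strand_symmetry(self, planted):
        g, truth, _ = planted
        chrom = "chr1"
        ct = truth.chroms[chrom]
        plus = dict(zip(ct.plus_pos[ct.plus_ctx == st.CPG],
                        ct.plus_p[ct.plus_ctx == st.CPG]))
        minus_cpg = ct.minus_ctx == st.CPG
        for pos, p in zip(ct.minus_pos[minus_cpg][:200],
                          ct.minus_p[minus_cpg][:200]):
            assert p == pytest.approx(plus[pos - 1])

    def test_female_x_elevated_male_not(self):
        diffs = {}
        for sex in ("female", "male"):
            cfg = SimConfig(seed=4, sex=sex, **TINY)
            g = build_genome(cfg)
            assign_expression(g, cfg)
            truth = plant_methylome(g, cfg)
            tf = truth.cpg_truth()
            diffs[sex] = (tf.loc[tf["chrom"] == "chrX", "p_true"].mean()
                          - tf.loc[tf["chrom"] != "chrX", "p_true"].mean())
        # the female inactivation shift dominates; the male difference is
        # residual composition noise of this tiny fixture genome
        assert diffs["female"] > 0.1
        assert abs(diffs["male"]) < diffs["female"] / 2

    def test_shared_truth_seed_shares_biology(self):
        base = dict(TINY)
        a = simulate_dataset(SimConfig(seed=100, truth_seed=50, **base))
        b = simulate_dataset(SimConfig(seed=200, truth_seed=50, **base))
        assert a.genome.chromosomes == b.genome.chromosomes
        pd.testing.assert_frame_equal(a.truth.to_frame(), b.truth.to_frame())
        # reads differ between the two individuals
        assert a.reads["liver"][0][1] != b.reads["liver"][0][1] or \
            len(a.reads["liver"]) != len(b.reads["liver"])


class TestSimulateReads:
    def make(self, seed=5, **overrides):
        cfg = SimConfig(seed=seed, **{**TINY, **overrides})
        g = build_genome(cfg)
        assign_expression(g, cfg)
        var = plant_variants(g, cfg)
        truth = plant_methylome(g, cfg)
        return g, truth, var, cfg

    def test_complete_conversion_reads_all_t(self):
        g, truth, var, cfg = self.make(conversion_rate=1.0)
        for ct in truth.chroms.values():  # force a fully unmethylated world
            ct.plus_p[:] = 0.0
            ct.minus_p[:] = 0.0
            ct.effect_p[:] = 0.0
        var = var.iloc[0:0]  # no SNPs: every fragment base matches reference
        sim = simulate_reads(g, truth, var, cfg)
        placed = sim.placements.set_index("read_id")
        for rid, seq in sim.reads["liver"][:300]:
            info = placed.loc[rid]
            frag = sim.reduced.fragments[info["frag_index"]]
            ref = sim.reduced.sequences[info["frag_index"]]
            read_frag = seq if info["strand"] == "+" else st.revcomp(seq)
            if info["strand"] == "+":
                assert read_frag == ref.translate(st.C2T)
            else:
                assert read_frag == ref.translate(st.G2A)

    def test_incomplete_conversion_rate_recovered(self):
        """With zero methylation, the fraction of unconverted cytosine
        read-bases matches 1 - conversion_rate binomially."""
        g, truth, var, cfg = self.make(conversion_rate=0.9427)
        for ct in truth.chroms.values():
            ct.plus_p[:] = 0.0
            ct.minus_p[:] = 0.0
            ct.effect_p[:] = 0.0
        sim = simulate_reads(g, truth, var.iloc[0:0], cfg)
        placed = sim.placements.set_index("read_id")
        n_c = n_total = 0
        for rid, seq in sim.reads["liver"]:
            info = placed.loc[rid]
            ref = sim.reduced.sequences[info["frag_index"]]
            read_frag = seq if info["strand"] == "+" else st.revcomp(seq)
            arr = np.frombuffer(read_frag, np.uint8)
            ref_arr = np.frombuffer(ref, np.uint8)
            if info["strand"] == "+":
                cols = ref_arr == st.C
                n_c += int((arr[cols] == st.C).sum())
            else:
                cols = ref_arr == st.G
                n_c += int((arr[cols] == st.G).sum())
            n_total += int(cols.sum())
            if n_total > 20_000:
                break
        assert n_total >= 10_000
        frac = n_c / n_total
        se = np.sqrt(0.0573 * (1 - 0.0573) / n_total)
        assert abs(frac - 0.0573) < 4 * se + 1e-3

    def test_monoallelic_counts_zero_on_one_side(self, small_sim):
        counts = small_sim.allelic_counts
        truth = {g.id: g.ase_class for g in small_sim.genome.genes}
        mono = counts[[truth[g] == "monoallelic" for g in counts["gene"]]]
        expressed = mono[mono["rna_ref"] + mono["rna_alt"] >= 10]
        assert len(expressed) > 0
        for gene, grp in expressed.groupby("gene"):
            assert (grp["rna_ref"] == 0).all() or (grp["rna_alt"] == 0).all()

    def test_zero_fragments_error(self):
        g = GenomeModel({"c": "AT" * 200}, {"c": "autosome"}, [], [], 1)
        cfg = SimConfig(seed=1, **TINY)
        truth = plant_methylome(g, cfg)
        with pytest.raises(SizingError):
            simulate_reads(g, truth, pd.DataFrame(columns=["chrom", "pos", "alt"]),
                           cfg)

    def test_depth_matches_placements(self, small_sim):
        """Per-fragment read counts in the truth placements match the
        emitted reads exactly (conservation)."""
        for tissue in small_sim.config.tissues:
            emitted = len(small_sim.reads[tissue])
            placed = (small_sim.placements["tissue"] == tissue).sum()
            assert emitted == placed
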