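"""Region construction, metagene profiles, densities, summaries and the
statistical dispatcher."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from rrbskit.errors import ParameterError
from rrbskit.regions import (assign_sites, build_regions, chromosome_summary,
                             compare_groups, coverage_bias_check,
                             dinucleotide_density, merge_intervals,
                             metagene_profile, subtract_intervals, tss_window)
from rrbskit.synthgenome import GeneModel


def gene(gid="g1", chrom="c", strand="+", exons=((0, 400), (600, 1000))):
    exons = [tuple(e) for e in exons]
    tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
    return GeneModel(gid, chrom, strand, tss, exons)


class TestBuildRegions:
    def test_minus_strand_tss_window(self):
        # 300 bp upstream of a minus-strand TSS lie above it
        assert tss_window(1000, "-") == (800, 1300)

    def test_plus_strand_tss_window(self):
        assert tss_window(1000, "+") == (700, 1200)

    def test_gene_body_five_prime_exclusion(self):
        g = gene(exons=[(0, 1000)])
        reg = build_regions([g], [], {"c": 20_000})
        body = reg["gene_body"].iloc[0]
        assert (body["start"], body["end"]) == (50, 1000)

    def test_minus_strand_body_exclusion(self):
        g = gene(strand="-", exons=[(0, 1000)])
        reg = build_regions([g], [], {"c": 20_000})
        body = reg["gene_body"].iloc[0]
        assert (body["start"], body["end"]) == (0, 950)

    def test_shores_truncated_between_close_cgis(self):
        # two CGIs 1,000 bp apart: shores must not overlap either island
        cgis = [("c", 5000, 5500), ("c", 6500, 7000)]
        reg = build_regions([], cgis, {"c": 20_000}, shore_width=2000)
        shores = list(zip(reg["CGS"]["start"], reg["CGS"]["end"]))
        for s, e in shores:
            for _, cs, ce in cgis:
                assert e <= cs or s >= ce
        # interval-arithmetic oracle for the inter-island gap
        assert (5500, 6500) in shores

    def test_exon_intron_partition(self, small_sim):
        reg = build_regions(small_sim.genome.genes, [],
                            small_sim.genome.chromosomes)
        ex = reg["exon"].groupby("provenance").apply(
            lambda d: (d["end"] - d["start"]).sum(), include_groups=False)
        intr = reg["intron"].groupby("provenance").apply(
            lambda d: (d["end"] - d["start"]).sum(), include_groups=False)
        for g in small_sim.genome.genes:
            span = g.span[1] - g.span[0]
            assert ex[g.id] + intr.get(g.id, 0) == span

    def test_truncation_warns(self):
        with pytest.warns(UserWarning):
            build_regions([], [("c", 0, 500)], {"c": 1_000}, shore_width=2000)


class TestAssignSites:
    def test_multi_label_and_intergenic(self):
        regions = {
            "CGI": pd.DataFrame([("c", 10, 20, ".", "CGI", "x")],
                                columns=["chrom", "start", "end", "strand",
                                         "name", "provenance"]),
            "exon": pd.DataFrame([("c", 15, 30, "+", "exon", "g")],
                                 columns=["chrom", "start", "end", "strand",
                                          "name", "provenance"]),
        }
        sites = pd.DataFrame({"chrom": ["c"] * 3, "pos": [17, 25, 50]})
        out = assign_sites(sites, regions)
        assert out.loc[0, "CGI"] and out.loc[0, "exon"]
        assert not out.loc[1, "CGI"] and out.loc[1, "exon"]
        assert out.loc[2, "intergenic"]

    def test_partition_counts(self):
        regions = {
            "CGI": pd.DataFrame([("c", 0, 10, ".", "CGI", "x")],
                                columns=["chrom", "start", "end", "strand",
                                         "name", "provenance"]),
            "CGS": pd.DataFrame([("c", 10, 20, ".", "CGS", "x")],
                                columns=["chrom", "start", "end", "strand",
                                         "name", "provenance"]),
        }
        sites = pd.DataFrame({"chrom": ["c"] * 30, "pos": np.arange(30)})
        out = assign_sites(sites, regions)
        assert out["CGI"].sum() + out["CGS"].sum() + out["intergenic"].sum() == 30


class TestMetagene:
    def test_single_site_single_anchor(self):
        sites = pd.DataFrame({"chrom": ["c"], "pos": [850], "level": [0.4]})
        prof = metagene_profile(sites, [("c", 1000, "+")], (-400, 400), 100)
        vals = prof.set_index("bin_start")["mean_level"]
        assert vals[-200] == pytest.approx(0.4)
        assert vals.drop(-200).isna().all()

    def test_orientation(self):
        sites = pd.DataFrame({"chrom": ["c"], "pos": [1100], "level": [0.9]})
        prof = metagene_profile(sites, [("c", 1000, "-")], (-400, 400), 100)
        vals = prof.set_index("bin_start")["mean_level"]
        assert vals[-100] == pytest.approx(0.9)  # downstream on minus strand

    def test_window_must_divide(self):
        with pytest.raises(ParameterError):
            metagene_profile(pd.DataFrame({"chrom": [], "pos": [], "level": []}),
                             [("c", 0, "+")], (-250, 200), 100)

    def test_uniform_methylome_is_flat(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(100_000, 20_000, replace=False))
        sites = pd.DataFrame({"chrom": "c", "pos": pos,
                              "level": rng.binomial(20, 0.5, pos.size) / 20})
        anchors = [("c", int(p), "+") for p in rng.integers(5000, 95_000, 50)]
        prof = metagene_profile(sites, anchors)
        se = 0.5 / np.sqrt(prof["n_sites"].clip(lower=1))
        assert ((prof["mean_level"] - 0.5).abs() <= 3 * se + 0.02).all()


class TestDensity:
    def regions_frame(self, seq, name="r"):
        return pd.DataFrame([("c", 0, len(seq), ".", name, "g")],
                            columns=["chrom", "start", "end", "strand",
                                     "name", "provenance"])

    def test_toy_cpg_density(self):
        out = dinucleotide_density({"c": "ACGCGT"}, self.regions_frame("ACGCGT"))
        assert out.iloc[0]["count"] == 2
        assert out.iloc[0]["density"] == pytest.approx(100 * 2 / 6)

    def test_toy_tpg_density_zero(self):
        out = dinucleotide_density({"c": "ACGCGT"},
                                   self.regions_frame("ACGCGT"), "TG")
        assert out.iloc[0]["density"] == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(hst.text(alphabet="ACGT", min_size=2, max_size=200),
           hst.sampled_from(["CG", "TG", "AG"]))
    def test_matches_substring_counter(self, seq, dinuc):
        # brute-force oracle: count starts of the dinucleotide inside the region
        out = dinucleotide_density({"c": seq}, self.regions_frame(seq), dinuc)
        expected = sum(seq[i:i + 2] == dinuc for i in range(len(seq) - 1))
        assert out.iloc[0]["count"] == expected

    def test_zero_length_region_skipped(self):
        reg = pd.DataFrame([("c", 5, 5, ".", "r", "g")],
                           columns=["chrom", "start", "end", "strand",
                                    "name", "provenance"])
        with pytest.warns(UserWarning):
            out = dinucleotide_density({"c": "ACGT" * 10}, reg)
        assert out.empty


class TestChromosomeSummary:
    def test_arithmetic(self):
        levels = pd.DataFrame({"chrom": "c", "pos": [1, 2, 3],
                               "level": [0.0, 0.05, 0.5]})
        summary, _ = chromosome_summary(levels, {"c": "autosome"})
        row = summary.iloc[0]
        assert row["pct_unmethylated"] == pytest.approx(100 / 3)
        assert row["pct_methylated"] == pytest.approx(100 / 3)
        assert row["mean_level_pct"] == pytest.approx(100 * 0.55 / 3)

    def test_female_x_elevated(self, default_run):
        sim, res, _ = default_run
        from rrbskit.pipeline import shared_levels_frame
        lv = shared_levels_frame(res)
        _, comps = chromosome_summary(lv, sim.genome.chrom_class)
        assert all(c.pvalue < 0.01 for c in comps.values())
        summary, _ = chromosome_summary(lv, sim.genome.chrom_class)
        x = summary[summary["chrom_class"] == "X"]["mean_level_pct"].mean()
        auto = summary[summary["chrom_class"] != "X"]["mean_level_pct"].mean()
        assert x > auto

    def test_male_x_null(self, male_run):
        sim, res = male_run
        from rrbskit.pipeline import shared_levels_frame
        lv = shared_levels_frame(res)
        _, comps = chromosome_summary(lv, sim.genome.chrom_class)
        assert all(c.pvalue > 0.05 for c in comps.values())


class TestCompareGroups:
    def test_normal_data_takes_t_test(self):
        rng = np.random.default_rng(1)
        res = compare_groups(rng.normal(0, 1, 80), rng.normal(0.1, 1, 80))
        assert "t-test" in res.test

    def test_skewed_data_takes_wilcoxon(self):
        rng = np.random.default_rng(1)
        res = compare_groups(rng.exponential(1, 200) ** 3,
                             rng.exponential(1, 200) ** 3)
        assert res.test == "wilcoxon rank-sum"

    def test_paired_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 2.5])
        with pytest.warns(UserWarning):
            res = compare_groups(a, a, paired=True)
        assert res.pvalue == 1.0

    def test_constant_input_nonparametric(self):
        with pytest.warns(UserWarning):
            res = compare_groups([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert res.test.startswith("wilcoxon")

    def test_minimum_group_size(self):
        with pytest.raises(ParameterError):
            compare_groups([1, 2], [1, 2, 3])

    def test_type_i_error_calibrated(self):
        """Under equal-mean Gaussian sampling the dispatcher's rejection
        rate at alpha = 0.05 stays near nominal."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            res = compare_groups(rng.normal(0, 1, 40), rng.normal(0, 1, 40))
            rejections += res.pvalue < 0.05
        assert 0.03 <= rejections / n_reps <= 0.07


class TestCoverageBias:
    def test_proportional_counts_rho_one(self, small_sim):
        g = small_sim.genome
        sites = []
        for chrom, seq in g.chromosomes.items():
            import rrbskit._seqtools as st
            n = st.cpg_starts(st.seq_array(seq)).size
            sites.append(pd.DataFrame({"chrom": chrom,
                                       "pos": np.arange(n // 2)}))
        out = coverage_bias_check(pd.concat(sites), g.chromosomes)
        assert out["rho"] == pytest.approx(1.0)

    def test_unbiased_simulation_correlates(self, default_run):
        sim, res, _ = default_run
        out = coverage_bias_check(res.shared_cpg, sim.genome.chromosomes)
        assert out["rho"] > 0.85


class TestIntervalHelpers:
    def test_merge(self):
        assert merge_intervals([(5, 8), (0, 3), (2, 6)]) == [(0, 8)]

    def test_subtract(self):
        assert subtract_intervals((0, 10), [(2, 4), (6, 8)]) == \
            [(0, 2), (4, 6), (8, 10)]
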