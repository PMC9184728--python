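"""Intragenic regions, responsive genes, DIC extraction, LC/HC, profiles."""

import numpy as np
import pandas as pd
import pytest

from dicpipe import sitecalls
from dicpipe.formats import Gene, GenomicInterval


def mk_sites(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"s{i}" for i in range(len(df))]
    df["strand"] = "."
    return df


class TestIntragenicRegions:
    def test_plus_strand_interval_arithmetic(self):
        g = Gene("g1", "chr1", "+", 0, 50_000)
        regions = sitecalls.derive_intragenic_regions([g])
        iv = regions.regions["g1"]
        assert (iv.start, iv.end) == (10_000, 40_000)

    @pytest.mark.parametrize("length", [15_000, 20_000])
    def test_short_genes_yield_nothing(self, length):
        g = Gene("g1", "chr1", "+", 0, length)
        regions = sitecalls.derive_intragenic_regions([g])
        assert "g1" not in regions.regions

    def test_just_over_cutoff_included(self):
        g = Gene("g1", "chr1", "+", 0, 21_000)
        regions = sitecalls.derive_intragenic_regions([g])
        iv = regions.regions["g1"]
        assert (iv.start, iv.end) == (10_000, 11_000)

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            sitecalls.derive_intragenic_regions([], flank=-1)

    def test_extra_exclusions_subtracted(self):
        g = Gene("g1", "chr1", "+", 0, 100_000)
        ex = [GenomicInterval("chr1", 40_000, 45_000)]
        regions = sitecalls.derive_intragenic_regions([g], extra_exclusions=ex)
        iv = regions.regions["g1"]  # largest remaining piece
        assert (iv.start, iv.end) == (45_000, 90_000)


class TestLocationClasses:
    genes = [Gene("g1", "chr1", "+", 100_000, 200_000)]

    def regions(self):
        return sitecalls.derive_intragenic_regions(self.genes)

    def test_three_classes(self):
        sites = mk_sites([("chr1", 100_300, 100_700),    # TSS + 500
                          ("chr1", 149_800, 150_200),    # mid body
                          ("chr1", 500_000, 500_400)])   # desert
        out = sitecalls.classify_site_location(sites, self.genes, self.regions())
        assert list(out["location"]) == ["aroundTSS", "intragenic", "intergenic"]
        assert out.loc[1, "host_gene"] == "g1"

    def test_overlapping_genes_nearest_tss_wins(self):
        genes = [Gene("a", "chr1", "+", 0, 100_000),
                 Gene("b", "chr1", "+", 40_000, 140_000)]
        regions = sitecalls.derive_intragenic_regions(genes)
        sites = mk_sites([("chr1", 54_800, 55_200)])  # summit 55 kb
        out = sitecalls.classify_site_location(sites, genes, regions)
        assert out.loc[0, "location"] == "intragenic"
        assert out.loc[0, "host_gene"] == "b"  # 15 kb to b's TSS vs 55 kb to a's


class TestResponsiveGenes:
    def table(self, rows):
        elong = pd.DataFrame(rows, columns=["gene_id", "ratio"])
        expr = pd.DataFrame({
            "gene_id": elong["gene_id"],
            "log2fc": [1.0, 0.0, -1.0][:len(elong)]})
        return elong, expr

    def test_threshold_semantics(self):
        elong = pd.DataFrame({"gene_id": ["a", "b", "c"],
                              "ratio": [1.3, 1.2, 1.5]})
        expr = pd.DataFrame({"gene_id": ["a", "b", "c"],
                             "log2fc": [1.0, 1.0, -1.0]})
        out = sitecalls.call_responsive_genes(elong, expr).set_index("gene_id")
        assert bool(out.loc["a", "responsive"])          # 1.3 > 1.2, lfc +
        assert not bool(out.loc["b", "responsive"])      # strict inequality
        assert not bool(out.loc["c", "responsive"])      # fails validation

    def test_single_table_gene_excluded_with_warning(self):
        elong = pd.DataFrame({"gene_id": ["a", "b"], "ratio": [1.5, 1.5]})
        expr = pd.DataFrame({"gene_id": ["a"], "log2fc": [1.0]})
        with pytest.warns(UserWarning, match="only one table"):
            out = sitecalls.call_responsive_genes(elong, expr)
        assert list(out["gene_id"]) == ["a"]


class TestExtractDics:
    def fixture(self):
        genes = [Gene("g1", "chr1", "+", 0, 100_000)]
        regions = sitecalls.derive_intragenic_regions(genes)
        sites = mk_sites([("chr1", 48_000, 51_500),   # width 3500
                          ("chr1", 49_000, 50_000),   # width 1000
                          ("chr1", 60_000, 61_000)])
        located = sitecalls.classify_site_location(sites, genes, regions)
        diff = sites.copy()
        diff["M"] = [-1.0, -0.6, -0.6]
        resp = pd.DataFrame({"gene_id": ["g1"], "responsive": [True]})
        return diff, located, resp

    def test_predicate_conjunction(self):
        diff, located, resp = self.fixture()
        out = sitecalls.extract_dics(diff, located, resp)
        assert list(out["is_dic"]) == [False, True, True]  # width cap on s0

    def test_nonresponsive_host_blocks_call(self):
        diff, located, resp = self.fixture()
        resp["responsive"] = False
        out = sitecalls.extract_dics(diff, located, resp)
        assert not out["is_dic"].any()

    def test_missing_m_value_raises(self):
        diff, located, resp = self.fixture()
        with pytest.raises(ValueError, match="missing M"):
            sitecalls.extract_dics(diff.iloc[:2], located, resp)

    def test_relaxing_any_predicate_grows_set(self, default_scene, diff_table,
                                              dic_calls):
        """The DIC set is a conjunction: dropping a predicate is monotone."""
        full = dic_calls
        base = full["is_dic"]
        for pred in ("pred_width", "pred_decreased", "pred_intragenic",
                     "pred_responsive"):
            others = [c for c in ("pred_width", "pred_decreased",
                                  "pred_intragenic", "pred_responsive")
                      if c != pred]
            relaxed = full[others].all(axis=1)
            assert (relaxed | ~base).all() and relaxed.sum() >= base.sum()

    def test_no_dic_near_tss_or_tes(self, default_scene, dic_calls):
        genes = {g.gene_id: g for g in default_scene.genes}
        for _, row in dic_calls[dic_calls["is_dic"]].iterrows():
            g = genes[row["host_gene"]]
            summit = (row["start"] + row["end"]) // 2
            assert abs(summit - g.tss) > 10_000
            assert abs(summit - g.tes) > 10_000

    def test_every_dic_host_responsive(self, default_scene, dic_calls):
        resp = set(default_scene.truth.responsive_genes)
        hosts = dic_calls.loc[dic_calls["is_dic"], "host_gene"]
        assert set(hosts) <= resp


class TestDensityAndSplit:
    def test_density_arithmetic(self):
        reads = {"chr1": np.arange(0, 1000, 10)}  # 100 reads in [0, 1000)
        sites = mk_sites([("chr1", 400, 600)])    # summit 500, window 500
        d = sitecalls.quantify_density(reads, sites, window=500,
                                       library_size=1e6)
        assert d[0] == 100.0
        d2 = sitecalls.quantify_density(reads, sites, window=500,
                                        library_size=2e6)
        assert d2[0] == 50.0

    def test_density_zero_reads(self):
        d = sitecalls.quantify_density({}, mk_sites([("chr1", 0, 10)]),
                                       window=100, library_size=1e6)
        assert d[0] == 0.0

    @pytest.mark.parametrize("kw", [dict(window=0), dict(library_size=0)])
    def test_density_validation(self, kw):
        args = dict(window=100, library_size=1e6)
        args.update(kw)
        with pytest.raises(ValueError):
            sitecalls.quantify_density({}, mk_sites([("chr1", 0, 10)]), **args)

    def test_explicit_cutoff_override(self):
        dics = mk_sites([("chr1", 0, 100), ("chr1", 200, 300)])
        out = sitecalls.split_lc_hc(dics, np.array([4.9, 5.1]),
                                    np.array([10.0, 10.0]), cutoff=5.0)
        assert list(out["subtype"]) == ["LC", "HC"]

    def test_identical_densities_error(self):
        dics = mk_sites([("chr1", 0, 100), ("chr1", 200, 300)])
        with pytest.raises(ValueError, match="identical"):
            sitecalls.split_lc_hc(dics, np.array([5.0, 5.0]),
                                  np.array([10.0, 10.0]))

    def test_rad21_filter_drops_sites(self):
        dics = mk_sites([("chr1", 0, 100), ("chr1", 200, 300),
                         ("chr1", 400, 500)])
        out = sitecalls.split_lc_hc(dics, np.array([1.0, 50.0, 2.0]),
                                    np.array([10.0, 10.0, 0.1]),
                                    min_rad21=1.0)
        assert len(out) == 2

    def test_monotone_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        dens = np.exp(rng.normal(np.where(rng.random(60) < 0.5, 0, 4), 0.3))
        dics = mk_sites([("chr1", i * 1000, i * 1000 + 100)
                         for i in range(60)])
        r = np.full(60, 10.0)
        s1 = sitecalls.split_lc_hc(dics, dens, r)["subtype"]
        s2 = sitecalls.split_lc_hc(dics, dens * 100, r)["subtype"]
        assert (s1 == s2).all()


class TestAggregateProfile:
    def test_constant_track_flat_profile(self):
        track = {"chr1": np.full(1000, 7.0)}
        sites = mk_sites([("chr1", 40_000, 41_000),
                          ("chr1", 60_000, 61_000)])
        prof = sitecalls.aggregate_profile(track, 100, sites, flank=2000,
                                           bin_size=100)
        np.testing.assert_allclose(prof.mean, 7.0)
        np.testing.assert_allclose(prof.ci_halfwidth, 0.0)

    def test_single_site_zero_width_ci(self):
        track = {"chr1": np.arange(1000.0)}
        sites = mk_sites([("chr1", 40_000, 41_000)])
        with pytest.warns(UserWarning, match="single site"):
            prof = sitecalls.aggregate_profile(track, 100, sites, flank=1000,
                                               bin_size=100)
        assert (prof.ci_halfwidth == 0).all()

    def test_minus_strand_mirrors_ramp(self):
        track = {"chr1": np.arange(1000.0)}
        plus = mk_sites([("chr1", 49_500, 50_500)])
        minus = plus.copy()
        minus["strand"] = "-"
        p1 = sitecalls.aggregate_profile(track, 100, plus, 2000, 100)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p2 = sitecalls.aggregate_profile(track, 100, minus, 2000, 100)
        np.testing.assert_allclose(p2.mean, p1.mean[::-1])

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError):
            sitecalls.aggregate_profile({}, 100, mk_sites([]), 1000, 100)


class TestPresence:
    def test_identical_sets_all_present(self):
        ref = mk_sites([("chr1", 0, 100), ("chr1", 200, 300)])
        pres, absent = sitecalls.compare_presence(
            ref, {"a": ref.copy(), "b": ref.copy()})
        assert pres.to_numpy().all() and len(absent) == 0

    def test_reference_only_sites_all_absent(self):
        ref = mk_sites([("chr1", 0, 100)])
        other = mk_sites([("chr2", 0, 100)])
        pres, absent = sitecalls.compare_presence(
            ref, {"a": other, "b": other.copy()})
        assert len(absent) == 1

    def test_partial_overlap_matches_enumeration(self):
        ref = mk_sites([("chr1", 0, 100), ("chr1", 200, 300),
                        ("chr1", 400, 500)])
        s1 = mk_sites([("chr1", 50, 150), ("chr1", 450, 460)])
        s2 = mk_sites([("chr1", 250, 260)])
        pres, absent = sitecalls.compare_presence(ref, {"s1": s1, "s2": s2},
                                                  case_samples=["s1", "s2"])
        # brute-force expectation per site
        assert list(pres["s1"]) == [True, False, True]
        assert list(pres["s2"]) == [False, True, False]
        assert len(absent) == 0

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            sitecalls.compare_presence(mk_sites([("chr1", 0, 1)]),
                                       {"a": mk_sites([("chr1", 0, 1)])})


class TestDensityExpressionCorrelation:
    def test_anti_monotone_rho(self):
        rho, p = sitecalls.correlate_site_expression(
            np.arange(10.0), -np.arange(10.0))
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sitecalls.correlate_site_expression(np.arange(5.0), np.ones(5))

    def test_hand_ranked_oracle(self):
        x = np.array([3.0, 1, 4, 1.5, 9, 2.6, 5, 3.5, 7, 8])
        y = np.array([2.0, 9, 1, 8, 0.5, 7, 3, 6, 2.5, 1.5])
        rho, p = sitecalls.correlate_site_expression(x, y)
        # independent oracle: Pearson on midranks
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            sitecalls.correlate_site_expression([1, 2], [2, 1])
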