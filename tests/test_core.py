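import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import build_meth, random_meth
from demeth import core
from oracles import profile_oracle, weighted_oracle


class TestWeightedMethylation:
    def test_direct_formula(self, meth_frame):
        meth = meth_frame([("chr1", 10, "+", "CGA", 5, 10, 1),
                           ("chr1", 20, "+", "CGA", 0, 10, 0)])
        assert core.weighted_methylation(meth, "CG").level == 0.25

    def test_saturation(self, meth_frame):
        meth = meth_frame([("chr1", 10, "+", "CGA", 10, 10, 1),
                           ("chr1", 20, "+", "CGA", 10, 10, 1)])
        assert core.weighted_methylation(meth, "CG").level == 1.0

    def test_no_covered_sites_is_undefined_not_zero(self, meth_frame):
        meth = meth_frame([("chr1", 10, "+", "CGA", 0, 0, 0)])
        w = core.weighted_methylation(meth, "CG")
        assert np.isnan(w.level) and w.n_sites == 0

    def test_region_membership_is_half_open_on_zero_based_position(self, meth_frame):
        # 1-based pos 101 has 0-based position 100: inside [100, 200), pos 201 not
        meth = meth_frame([("chr1", 101, "+", "CGA", 10, 10, 1),
                           ("chr1", 201, "+", "CGA", 0, 10, 0)])
        w = core.weighted_methylation(meth, "CG", region=("chr1", 100, 200))
        assert w.level == 1.0 and w.n_sites == 1

    def test_matches_accumulation_oracle_on_random_sites(self, rng):
        meth = random_meth(rng, n=1000)
        for ctx in ("CG", "CHG", "CHH", "ALL"):
            got = core.weighted_methylation(meth, ctx).level
            np.testing.assert_allclose(got, weighted_oracle(meth, ctx))

    def test_all_context_level_lies_between_context_extremes(self, rng):
        for seed in range(5):
            meth = random_meth(np.random.default_rng(seed), n=300)
            per_ctx = [core.weighted_methylation(meth, c).level
                       for c in ("CG", "CHG", "CHH")]
            defined = [x for x in per_ctx if not np.isnan(x)]
            pooled = core.weighted_methylation(meth, "ALL").level
            assert min(defined) - 1e-12 <= pooled <= max(defined) + 1e-12

    def test_union_of_disjoint_regions_pools_by_counts(self, rng):
        meth = random_meth(rng, n=400, max_pos=1000)
        parts = [("chr1", 0, 300), ("chr1", 300, 700), ("chr1", 700, 1000)]
        mc = tot = 0
        for region in parts:
            w = core.weighted_methylation(meth, "ALL", region)
            mc, tot = mc + w.mc, tot + w.total
        whole = core.weighted_methylation(meth, "ALL", ("chr1", 0, 1000))
        assert (mc, tot) == (whole.mc, whole.total)


class TestMakeWindows:
    def test_final_partial_tile_retained(self):
        w = core.make_windows({"chr1": 250}, 100)
        assert list(zip(w["start"], w["end"])) == [(0, 100), (100, 200), (200, 250)]

    def test_exact_fit_single_window(self):
        w = core.make_windows({"chr1": 100}, 100)
        assert list(zip(w["start"], w["end"])) == [(0, 100)]

    @given(length=st.integers(1, 10_000), window=st.integers(1, 3_000))
    @settings(max_examples=50, deadline=None)
    def test_windows_partition_the_chromosome(self, length, window):
        w = core.make_windows({"chr1": length}, window)
        assert (w["end"] - w["start"]).sum() == length
        assert (w["start"].to_numpy()[1:] == w["end"].to_numpy()[:-1]).all()


class TestChromosomeProfile:
    def test_homogeneous_sites_give_uniform_levels(self, meth_frame):
        rows = [("chr1", p, "+", "CGA", 9, 10, 1) for p in range(1, 501, 10)]
        meth = meth_frame(rows)
        prof = core.chromosome_profile(meth, {"chr1": 500}, window_bp=100)
        np.testing.assert_allclose(prof["level_CG"], 0.9)

    def test_empty_window_is_undefined_with_zero_sites(self, meth_frame):
        meth = meth_frame([("chr1", 5, "+", "CGA", 3, 10, 1)])
        prof = core.chromosome_profile(meth, {"chr1": 300}, window_bp=100)
        assert np.isnan(prof.loc[1, "level_CG"]) and prof.loc[1, "n_CG"] == 0

    def test_matches_per_window_oracle(self, rng):
        meth = random_meth(rng, n=400, max_pos=1000)
        prof = core.chromosome_profile(meth, {"chr1": 1000}, window_bp=100)
        for ctx in ("CG", "CHG", "CHH"):
            expected = profile_oracle(meth, {"chr1": 1000}, 100, ctx)
            np.testing.assert_allclose(prof[f"level_{ctx}"], expected)

    def test_invariant_to_input_record_order(self, rng):
        meth = random_meth(rng, n=300, max_pos=1000)
        shuffled = meth.sample(frac=1.0, random_state=1)
        a = core.chromosome_profile(meth, {"chr1": 1000}, 100)
        b = core.chromosome_profile(shuffled, {"chr1": 1000}, 100)
        pd.testing.assert_frame_equal(a, b)


class TestRelativeProfile:
    def profile_of(self, meth):
        return core.chromosome_profile(meth, {"chr1": 300}, 100)

    def test_sample_relative_to_itself_is_one(self, rng):
        meth = random_meth(rng, n=200, max_pos=300)
        prof = self.profile_of(meth)
        rel = core.relative_profile(prof, prof)
        for ctx in ("CG", "CHG", "CHH"):
            vals = rel[f"ratio_{ctx}"].dropna()
            np.testing.assert_allclose(vals, 1.0)

    def test_ratio_arithmetic(self, meth_frame):
        t = self.profile_of(meth_frame([("chr1", 5, "+", "CGA", 2, 10, 1)]))
        c = self.profile_of(meth_frame([("chr1", 5, "+", "CGA", 4, 10, 1)]))
        rel = core.relative_profile(t, c)
        assert rel.loc[0, "ratio_CG"] == 0.5

    def test_zero_control_is_undefined_not_infinity(self, meth_frame):
        t = self.profile_of(meth_frame([("chr1", 5, "+", "CGA", 2, 10, 1)]))
        c = self.profile_of(meth_frame([("chr1", 5, "+", "CGA", 0, 10, 0)]))
        rel = core.relative_profile(t, c)
        assert np.isnan(rel.loc[0, "ratio_CG"])

    def test_mismatched_grids_rejected(self, meth_frame):
        meth = meth_frame([("chr1", 5, "+", "CGA", 2, 10, 1)])
        a = core.chromosome_profile(meth, {"chr1": 300}, 100)
        b = core.chromosome_profile(meth, {"chr1": 300}, 150)
        with pytest.raises(ValueError, match="grid"):
            core.relative_profile(a, b)


class TestSiteLevelDistribution:
    def test_fraction_fully_methylated(self, meth_frame):
        meth = meth_frame([("chr1", 1, "+", "CGA", 10, 10, 1),
                           ("chr1", 2, "+", "CGA", 8, 8, 1),
                           ("chr1", 3, "+", "CGA", 5, 10, 1)])
        dist = core.site_level_distribution(meth, "CG")
        assert dist.fraction_fully_methylated == pytest.approx(2 / 3)

    def test_unmethylated_sites_mass_at_zero(self, meth_frame):
        meth = meth_frame([("chr1", p, "+", "CGA", 0, 10, 0) for p in (1, 2, 3)])
        dist = core.site_level_distribution(meth, "CG")
        assert dist.density[0] == 1.0
        assert dist.fraction_fully_methylated == 0.0

    def test_only_methylated_sites_restricts_to_calls(self, meth_frame):
        meth = meth_frame([("chr1", 1, "+", "CGA", 10, 10, 1),
                           ("chr1", 2, "+", "CGA", 0, 10, 0)])
        dist = core.site_level_distribution(meth, "CG", only_methylated_sites=True)
        assert dist.n_sites == 1 and dist.fraction_fully_methylated == 1.0

    def test_histogram_mass_sums_to_one(self, rng):
        meth = random_meth(rng, n=500)
        meth = meth[meth["total"] > 0]
        dist = core.site_level_distribution(meth, "CHH")
        assert dist.density.sum() == pytest.approx(1.0)

    def test_no_qualifying_sites_is_error(self, meth_frame):
        meth = meth_frame([("chr1", 1, "+", "CGA", 0, 0, 0)])
        with pytest.raises(ValueError):
            core.site_level_distribution(meth, "CG")


class TestPairwiseHighMethWindows:
    def test_filter_keeps_windows_at_or_above_threshold(self, meth_frame):
        c = core.chromosome_profile(
            meth_frame([("chr1", 5, "+", "CGA", 6, 10, 1),
                        ("chr1", 105, "+", "CGA", 4, 10, 1)]), {"chr1": 200}, 100)
        t = core.chromosome_profile(
            meth_frame([("chr1", 5, "+", "CGA", 3, 10, 1),
                        ("chr1", 105, "+", "CGA", 2, 10, 1)]), {"chr1": 200}, 100)
        pairs = core.pairwise_high_meth_windows(t, c, "CG", 0.5)
        assert len(pairs) == 1
        assert pairs.loc[0, "control_level"] == 0.6
        assert pairs.loc[0, "ratio"] == 0.5

    def test_identical_samples_lie_on_unit_slope(self, rng):
        meth = random_meth(rng, n=300, max_pos=1000)
        prof = core.chromosome_profile(meth, {"chr1": 1000}, 100)
        pairs = core.pairwise_high_meth_windows(prof, prof, "CG", 0.3)
        np.testing.assert_allclose(pairs["ratio"], 1.0)


class TestPericentromerePartition:
    def test_midpoint_inside_interval_is_pericentromeric(self):
        wins = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        peri, arm = core.partition_pericentromere(wins, {"chr1": (50, 200)})
        assert len(peri) == 1 and len(arm) == 0

    def test_disjoint_window_is_arm(self):
        wins = pd.DataFrame({"chrom": ["chr1"], "start": [300], "end": [400]})
        peri, arm = core.partition_pericentromere(wins, {"chr1": (50, 200)})
        assert len(peri) == 0 and len(arm) == 1

    def test_every_window_in_exactly_one_set(self):
        wins = core.make_windows({"chr1": 1000, "chr2": 500}, 130)
        peri, arm = core.partition_pericentromere(wins, {"chr1": (200, 700)})
        assert len(peri) + len(arm) == len(wins)
        both = pd.merge(peri, arm, on=["chrom", "start", "end"])
        assert len(both) == 0


class TestFeatureMethylation:
    def test_counts_match_region_statistic(self, rng):
        meth = random_meth(rng, n=400, max_pos=2000)
        feats = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [100, 900], "end": [600, 1500],
            "strand": ["+", "-"], "feature_id": ["a", "b"],
            "kind": ["region", "region"], "te_family": ["", ""]})
        stats = core.feature_methylation(meth, feats)
        for i, row in feats.iterrows():
            w = core.weighted_methylation(
                meth, "CG", (row["chrom"], row["start"], row["end"]))
            assert stats.loc[i, "mc_CG"] == w.mc
            assert stats.loc[i, "total_CG"] == w.total
            assert stats.loc[i, "n_CG"] == w.n_sites
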