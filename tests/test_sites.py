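"""Site-level analyses: stack-ups, mean EV1, quadrants, randomised controls."""

import numpy as np
import pandas as pd
import pytest

from compartshift import (
    BinnedTrack,
    CompartmentTrack,
    GenomeSpec,
    SimParams,
    SiteSet,
    common_intervals,
    cross_line_quadrants,
    generate_sites,
    mean_profile,
    quadrant_classify,
    randomize_sites,
    rescue_group_compare,
    simulate_track,
    site_expression,
    site_mean_ev1,
    stackup,
)


def sites_from(rows):
    return SiteSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


@pytest.fixture
def genome10():
    return GenomeSpec((("c", 3_000_000),), 10_000)


class TestStackup:
    def test_delta_at_midpoint_hits_central_column(self, genome10):
        vals = np.zeros(genome10.n_bins)
        vals[100] = 5.0  # bp 1,000,000-1,010,000
        track = BinnedTrack(genome10, vals, "zscore")
        ss = sites_from([("c", 950_000, 1_060_000)])  # midpoint 1,005,000 in bin 100
        mat, _ = stackup(track, ss, flank=100_000)
        assert mat.shape == (1, 21)
        assert mat[0, 10] == 5.0

    def test_all_rows_same_width(self, genome10):
        track = BinnedTrack(genome10, np.zeros(genome10.n_bins), "zscore")
        ss = sites_from([("c", 0, 50_000), ("c", 1_000_000, 1_400_000)])
        mat, _ = stackup(track, ss, flank=200_000)
        assert mat.shape == (2, 2 * 20 + 1)

    def test_rows_sorted_by_size(self, genome10):
        track = BinnedTrack(genome10, np.zeros(genome10.n_bins), "zscore")
        ss = sites_from([("c", 0, 50_000), ("c", 1_000_000, 1_400_000),
                         ("c", 2_000_000, 2_100_000)])
        _, ordered = stackup(track, ss, flank=100_000)
        assert ordered["size"].is_monotonic_decreasing

    def test_out_of_chromosome_cells_missing(self, genome10):
        track = BinnedTrack(genome10, np.ones(genome10.n_bins), "zscore")
        ss = sites_from([("c", 0, 20_000)])  # midpoint near chromosome start
        mat, _ = stackup(track, ss, flank=100_000)
        assert np.isnan(mat[0, 0])
        assert np.isfinite(mat[0, -1])


class TestMeanProfile:
    def test_single_row_equals_itself(self):
        stack = np.array([[1.0, 2.0, 3.0]])
        sites = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100_000],
                              "size": [100_000]})
        np.testing.assert_array_equal(mean_profile(stack, sites), stack[0])

    def test_empty_size_window_warns_and_returns_empty(self):
        stack = np.ones((1, 3))
        sites = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [500_000],
                              "size": [500_000]})
        with pytest.warns(UserWarning):
            out = mean_profile(stack, sites, size_window=(60_000, 160_000))
        assert out.size == 0

    def test_planted_boundary_enrichment_peaks_flank_the_centre(self):
        g = GenomeSpec((("c", 20_000_000),), 50_000)
        from compartshift import (cpm_normalize, generate_compartment_profile,
                                  log2_ip_over_input, zscore_per_chromosome)

        truth = generate_compartment_profile(g, 1_000_000, 0.0, seed=1)
        # all sites the same length so flank peaks align
        starts = np.arange(500_000, 19_000_000, 1_500_000)
        ss = sites_from([("c", int(s), int(s) + 100_000) for s in starts])
        params = SimParams(sequencing_depth=4e6, ip_effect=1.5)
        ip, inp = simulate_track(truth, ss, params, seed=2,
                                 compartment_effect=False)
        z = zscore_per_chromosome(log2_ip_over_input(cpm_normalize(ip),
                                                     cpm_normalize(inp)))
        mat, ordered = stackup(z, ss, flank=200_000)
        prof = mean_profile(mat, ordered, size_window=(60_000, 160_000))
        centre = prof.size // 2
        # boundaries sit +-50 kb (5 bins) off-centre
        flank_mean = (prof[centre - 5] + prof[centre + 5]) / 2
        far_mean = (prof[0] + prof[-1]) / 2
        assert flank_mean > far_mean


class TestSiteMeanEv1:
    def _ev(self, values, res=50_000):
        g = GenomeSpec((("c", len(values) * res),), res)
        return CompartmentTrack(g, np.asarray(values, dtype=float))

    def test_site_within_one_bin_inherits_value(self):
        ev = self._ev([0.7, -0.2])
        ss = sites_from([("c", 10_000, 40_000)])
        assert site_mean_ev1(ev, ss)[0] == pytest.approx(0.7)

    def test_site_spanning_opposite_bins_averages_to_zero(self):
        ev = self._ev([1.0, -1.0])
        ss = sites_from([("c", 0, 100_000)])
        assert site_mean_ev1(ev, ss)[0] == pytest.approx(0.0)

    def test_half_na_site_uses_defined_half(self):
        ev = self._ev([0.6, np.nan])
        ss = sites_from([("c", 0, 100_000)])
        assert site_mean_ev1(ev, ss)[0] == pytest.approx(0.6)

    def test_mostly_na_site_is_na(self):
        ev = self._ev([0.6, np.nan, np.nan, np.nan])
        ss = sites_from([("c", 0, 200_000)])
        assert np.isnan(site_mean_ev1(ev, ss, min_defined_frac=0.5)[0])


class TestQuadrantClassify:
    def test_sign_quadrant_mapping(self):
        res = quadrant_classify([0.5, -0.1, 0.5, -0.3], [-0.2, 0.3, 0.4, -0.6])
        assert list(res.labels) == ["A-to-B", "B-to-A", "A-stable", "B-stable"]

    def test_zero_or_nan_is_na(self):
        res = quadrant_classify([0.0, np.nan], [0.5, 0.5])
        assert list(res.labels) == ["NA", "NA"]

    def test_proportions_sum_to_one_over_scored(self):
        rng = np.random.default_rng(3)
        res = quadrant_classify(rng.normal(size=50), rng.normal(size=50))
        total = sum(res.proportions[k] for k in
                    ("A-to-B", "B-to-A", "A-stable", "B-stable"))
        assert total == pytest.approx(1.0)

    def test_condition_swap_is_antisymmetric(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=30), rng.normal(size=30)
        fwd = quadrant_classify(a, b)
        rev = quadrant_classify(b, a)
        swap = {"A-to-B": "B-to-A", "B-to-A": "A-to-B"}
        assert [swap.get(l, l) for l in fwd.labels] == list(rev.labels)

    def test_cross_line_summary_reports_mean_and_sd(self):
        pairs = [([0.5, -0.5], [-0.5, -0.5]), ([0.5, -0.5], [0.5, -0.5])]
        table = cross_line_quadrants(pairs)
        row = table.set_index("category").loc["A-to-B"]
        assert row["mean"] == pytest.approx(0.25)
        assert row["sd"] == pytest.approx(0.25)


class TestRandomizeSites:
    def test_length_multiset_preserved(self):
        g = GenomeSpec((("c", 50_000_000), ("d", 30_000_000)), 50_000)
        ss = generate_sites(g, 40, (30_000, 200_000), seed=1)
        rand = randomize_sites(ss, g, seed=2)
        assert sorted(rand.sizes) == sorted(ss.sizes)

    def test_seeded_determinism(self):
        g = GenomeSpec((("c", 50_000_000),), 50_000)
        ss = generate_sites(g, 20, (30_000, 100_000), seed=1)
        a = randomize_sites(ss, g, seed=5)
        b = randomize_sites(ss, g, seed=5)
        pd.testing.assert_frame_equal(a.intervals, b.intervals)

    def test_avoids_masked_bins(self):
        g = GenomeSpec((("c", 10_000_000),), 50_000)
        mask = np.zeros(g.n_bins, dtype=bool)
        mask[:100] = True  # first 5 Mb masked
        ss = sites_from([("c", int(s), int(s) + 60_000)
                         for s in range(6_000_000, 9_000_000, 300_000)])
        rand = randomize_sites(ss, g, mask=mask, seed=3)
        assert (rand.intervals["start"] >= 5_000_000).all()

    def test_compartment_label_counts_matched(self):
        g = GenomeSpec((("c", 50_000_000),), 50_000)
        rng = np.random.default_rng(7)
        ev = CompartmentTrack(g, np.repeat(rng.choice([-0.5, 0.5], g.n_bins // 10),
                                           10)[: g.n_bins])
        ss = generate_sites(g, 30, (30_000, 120_000), seed=4)
        rand = randomize_sites(ss, g, seed=5, match_compartment=ev)
        from compartshift.sites import _site_compartment_labels

        orig = np.unique(_site_compartment_labels(ss, ev), return_counts=True)
        new = np.unique(_site_compartment_labels(rand, ev), return_counts=True)
        assert dict(zip(*orig)) == dict(zip(*new))

    def test_infeasible_placement_raises(self):
        g = GenomeSpec((("c", 1_000_000),), 50_000)
        mask = np.ones(g.n_bins, dtype=bool)
        ss = sites_from([("c", 0, 100_000)])
        with pytest.raises(RuntimeError):
            randomize_sites(ss, g, mask=mask, seed=1, max_tries=20)


class TestSiteExpression:
    def test_zero_track_gives_zero(self, genome10):
        rna = BinnedTrack(genome10, np.zeros(genome10.n_bins), "log2_cpm1")
        ss = sites_from([("c", 100_000, 300_000)])
        assert site_expression(rna, ss)[0] == 0.0

    def test_uniform_track_returns_value(self, genome10):
        rna = BinnedTrack(genome10, np.full(genome10.n_bins, 2.5), "log2_cpm1")
        ss = sites_from([("c", 100_000, 300_000), ("c", 1_000_000, 1_100_000)])
        np.testing.assert_allclose(site_expression(rna, ss), 2.5)

    def test_local_signal_raises_only_own_site(self, genome10):
        vals = np.zeros(genome10.n_bins)
        vals[10:20] = 4.0
        rna = BinnedTrack(genome10, vals, "log2_cpm1")
        ss = sites_from([("c", 100_000, 200_000), ("c", 1_000_000, 1_100_000)])
        means = site_expression(rna, ss)
        assert means[0] == 4.0 and means[1] == 0.0


class TestRescueGroupCompare:
    def test_identical_groups_not_significant(self):
        labels = np.array(["B-to-A"] * 10 + ["B-stable"] * 10)
        vals = np.concatenate([np.arange(10.0), np.arange(10.0)])
        out = rescue_group_compare(labels, {"wt": vals, "ko": vals})
        tested = out[out["status"] == "tested"]
        assert (tested["p"] > 0.5).all()

    def test_planted_shift_detected_after_bh(self):
        rng = np.random.default_rng(11)
        labels = np.array(["B-to-A"] * 21 + ["B-stable"] * 60)
        base = rng.normal(0, 1, labels.size)
        shifted = base.copy()
        shifted[labels == "B-to-A"] += 2.0
        out = rescue_group_compare(labels, {"wt": base, "ko": shifted})
        row = out[out["comparison"] == "B-to-A-vs-B-stable@ko"].iloc[0]
        assert row["q"] <= 0.05

    def test_small_group_skipped_and_flagged(self):
        labels = np.array(["B-to-A"] * 1 + ["B-stable"] * 5)
        vals = np.arange(6.0)
        out = rescue_group_compare(labels, {"wt": vals})
        assert (out["status"] == "skipped").any()


class TestCommonIntervals:
    def test_self_intersection_is_identity(self):
        a = sites_from([("c", 0, 100), ("c", 200, 300)])
        out = common_intervals(a, a)
        assert out.intervals[["chrom", "start", "end"]].values.tolist() == [
            ["c", 0, 100], ["c", 200, 300]]

    def test_disjoint_sets_give_empty(self):
        a = sites_from([("c", 0, 100)])
        b = sites_from([("c", 100, 200)])  # half-open: no overlap
        assert len(common_intervals(a, b)) == 0

    def test_half_open_overlap_arithmetic(self):
        a = sites_from([("c", 0, 100)])
        b = sites_from([("c", 50, 150)])
        out = common_intervals(a, b)
        assert out.intervals[["start", "end"]].values.tolist() == [[50, 100]]

    def test_three_way_intersection(self):
        a = sites_from([("c", 0, 300)])
        b = sites_from([("c", 100, 400)])
        c = sites_from([("c", 150, 250)])
        out = common_intervals(a, b, c)
        assert out.intervals[["start", "end"]].values.tolist() == [[150, 250]]
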