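"""Contact-map I/O, masking, balancing, expected/O-E, P(s) and QC."""

import numpy as np
import pandas as pd
import pytest

from compartshift import (
    ContactMap,
    GenomeSpec,
    apply_blacklist,
    cis_trans_ratio,
    differential_map,
    expected_cis,
    ice_normalize,
    load_matrix,
    observed_over_expected,
    ps_curve,
    save_matrix,
)
from conftest import make_uniform_map


@pytest.fixture
def genome():
    return GenomeSpec((("chr1", 500_000), ("chr2", 300_000)), 100_000)


class TestLoadMatrix:
    def test_empty_file_gives_zero_map(self, genome, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("")
        cm = load_matrix(path, genome, 100_000)
        assert all(cm.matrices[c].sum() == 0 for c in genome.chrom_names)

    def test_entries_are_mirrored(self, genome, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("chr1\t0\t200000\t7\n")
        cm = load_matrix(path, genome, 100_000)
        assert cm.matrices["chr1"][0, 2] == 7
        assert cm.matrices["chr1"][2, 0] == 7

    def test_duplicate_triplets_summed(self, genome, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("chr1\t0\t100000\t2\nchr1\t0\t100000\t3\n")
        cm = load_matrix(path, genome, 100_000)
        assert cm.matrices["chr1"][0, 1] == 5

    def test_out_of_bounds_coordinate_names_line(self, genome, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("chr1\t0\t100000\t2\nchr1\t0\t900000\t1\n")
        with pytest.raises(ValueError, match="line 2"):
            load_matrix(path, genome, 100_000)

    def test_save_load_round_trip(self, genome, tmp_path):
        cm = make_uniform_map(genome, 3.0)
        save_matrix(cm, tmp_path / "m.tsv")
        back = load_matrix(tmp_path / "m.tsv", genome, 100_000)
        for chrom in genome.chrom_names:
            np.testing.assert_allclose(back.matrices[chrom], cm.matrices[chrom])


class TestBlacklist:
    def test_empty_blacklist_is_identity(self, genome):
        cm = make_uniform_map(genome)
        out = apply_blacklist(cm, pd.DataFrame(columns=["chrom", "start", "end"]))
        np.testing.assert_array_equal(out.matrices["chr1"], cm.matrices["chr1"])
        assert not out.mask.any()

    def test_region_zeroes_row_and_column(self, genome):
        cm = make_uniform_map(genome)
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [210_000], "end": [220_000]})
        out = apply_blacklist(cm, bl)
        assert out.matrices["chr1"][2, :].sum() == 0
        assert out.matrices["chr1"][:, 2].sum() == 0
        assert out.mask[2]

    def test_region_straddling_two_bins_masks_both(self, genome):
        cm = make_uniform_map(genome)
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [190_000], "end": [210_000]})
        out = apply_blacklist(cm, bl)
        assert out.mask[1] and out.mask[2]
        assert not out.mask[0] and not out.mask[3]

    def test_masking_is_idempotent(self, genome):
        cm = make_uniform_map(genome)
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000]})
        once = apply_blacklist(cm, bl)
        twice = apply_blacklist(once, bl)
        np.testing.assert_array_equal(once.mask, twice.mask)
        np.testing.assert_array_equal(once.matrices["chr1"], twice.matrices["chr1"])


class TestIceNormalize:
    def test_equal_marginals_give_unit_weights(self, genome):
        cm = make_uniform_map(genome, 2.0)
        out = ice_normalize(cm, n_iter=1)
        ok = ~out.mask
        np.testing.assert_allclose(out.weights[ok], 1.0)

    def test_single_iteration_matches_hand_computation(self):
        # counts with marginals (6, 4, 6): one pass gives w ~ 1/marginal,
        # normalised to mean one, and c' = c * w_i * w_j
        g = GenomeSpec((("c", 3),), 1)
        m = np.array([[0.0, 2, 4], [2, 0, 2], [4, 2, 0]])
        out = ice_normalize(ContactMap(g, {"c": m}), n_iter=1)
        marg = m.sum(1)
        w_expected = (1 / marg) / np.mean(1 / marg)
        np.testing.assert_allclose(out.weights, w_expected)
        np.testing.assert_allclose(out.balanced("c"),
                                   m * np.outer(w_expected, w_expected))

    def test_tol_mode_converges_marginals(self):
        rng = np.random.default_rng(0)
        n = 50
        raw = np.triu(rng.poisson(8, (n, n)).astype(float), 1)
        raw = raw + raw.T
        g = GenomeSpec((("c", n),), 1)
        out = ice_normalize(ContactMap(g, {"c": raw}), tol=1e-5)
        marg = np.nansum(out.balanced("c"), axis=1)[~out.mask]
        assert marg.std() / marg.mean() < 1e-4

    def test_zero_marginal_bins_get_masked(self):
        g = GenomeSpec((("c", 4),), 1)
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 5.0
        m[0, 3] = m[3, 0] = 2.0
        m[1, 3] = m[3, 1] = 3.0
        out = ice_normalize(ContactMap(g, {"c": m}), tol=1e-6)
        assert out.mask[2]
        assert np.isnan(out.weights[2])

    def test_all_masked_raises(self):
        g = GenomeSpec((("c", 3),), 1)
        cm = ContactMap(g, {"c": np.zeros((3, 3))}, mask=np.ones(3, dtype=bool))
        with pytest.raises(ValueError):
            ice_normalize(cm)


class TestExpectedAndOe:
    def test_uniform_map_has_flat_expected(self, genome):
        cm = ice_normalize(make_uniform_map(genome, 3.0), n_iter=1)
        exp = expected_cis(cm)
        for vals in exp.values:
            finite = vals[np.isfinite(vals)]
            np.testing.assert_allclose(finite, finite[0])

    def test_masking_does_not_change_uniform_expected(self, genome):
        cm = ice_normalize(make_uniform_map(genome, 3.0), n_iter=1)
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [200_000], "end": [250_000]})
        masked = ice_normalize(apply_blacklist(make_uniform_map(genome, 3.0), bl),
                               n_iter=1)
        e_full = expected_cis(cm).values[0]
        e_masked = expected_cis(masked).values[0]
        ok = np.isfinite(e_full) & np.isfinite(e_masked)
        np.testing.assert_allclose(e_full[ok], e_masked[ok])

    def test_oe_of_own_expected_is_one(self, genome):
        cm = ice_normalize(make_uniform_map(genome, 3.0), n_iter=1)
        oe = observed_over_expected(cm, expected_cis(cm))
        for chrom in genome.chrom_names:
            vals = oe.matrices[chrom]
            np.testing.assert_allclose(vals[np.isfinite(vals)], 1.0)

    def test_oe_per_distance_mean_is_one_on_random_map(self):
        rng = np.random.default_rng(1)
        n = 60
        raw = np.triu(rng.poisson(6, (n, n)).astype(float), 1)
        raw = raw + raw.T
        g = GenomeSpec((("c", n),), 1)
        cm = ice_normalize(ContactMap(g, {"c": raw}), tol=1e-6)
        oe = observed_over_expected(cm, expected_cis(cm))
        m = oe.matrices["c"]
        for d in range(1, n):
            diag = np.diagonal(m, d)
            diag = diag[np.isfinite(diag)]
            if diag.size:
                assert np.mean(diag) == pytest.approx(1.0, abs=1e-9)


class TestPsCurve:
    def test_uniform_arm_is_flat(self, genome):
        cm = ice_normalize(make_uniform_map(genome, 3.0), n_iter=1)
        ps = ps_curve(cm)
        np.testing.assert_allclose(ps.ps, ps.ps[0])

    def test_slope_recovers_decay_exponent(self):
        from compartshift import SimParams, simulate_tads

        g = GenomeSpec((("chr1", 20_000_000),), 10_000)
        cm, _ = simulate_tads(g, 20_000_000, 1.0, SimParams(sequencing_depth=5e6),
                              seed=7)
        bal = ice_normalize(cm, tol=1e-5)
        slope = ps_curve(bal).slope(50_000, 5_000_000)
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_two_identical_arms_aggregate_to_one(self):
        g1 = GenomeSpec((("c1", 40),), 1)
        g2 = GenomeSpec((("c1", 40), ("c2", 40)), 1)
        m = np.triu(np.fromfunction(lambda i, j: 10.0 / (1 + abs(i - j)), (40, 40)), 1)
        m = m + m.T
        one = ContactMap(g1, {"c1": m.copy()})
        one.weights = np.ones(40)
        two = ContactMap(g2, {"c1": m.copy(), "c2": m.copy()})
        two.weights = np.ones(80)
        np.testing.assert_allclose(ps_curve(one).ps, ps_curve(two).ps)


class TestCisTransRatio:
    def test_no_trans_flagged_undefined(self, genome):
        qc = cis_trans_ratio(make_uniform_map(genome, 1.0, trans=0.0))
        assert qc["undefined"] and np.isinf(qc["cis_trans_ratio"])

    def test_threshold_distance_is_inclusive(self):
        g = GenomeSpec((("c", 400_000),), 10_000)
        cm = ContactMap.zeros(g)
        cm.matrices["c"][0, 2] = cm.matrices["c"][2, 0] = 5.0  # 20 kb apart
        cm.matrices["c"][0, 3] = cm.matrices["c"][3, 0] = 7.0  # 30 kb apart
        qc = cis_trans_ratio(cm, threshold=20_000)
        assert qc["short_cis"] == 5.0
        assert qc["long_cis"] == 7.0

    def test_known_cis_trans_ratio_recovered(self):
        from compartshift import SimParams, generate_compartment_profile, simulate_hic

        g = GenomeSpec((("chr1", 20_000_000),), 50_000)
        truth = generate_compartment_profile(g, 1_000_000, 0.0, seed=1)
        cm = simulate_hic(truth, SimParams(sequencing_depth=9e5, trans_over_cis=1 / 9),
                          seed=3)
        qc = cis_trans_ratio(cm)
        assert qc["cis_trans_ratio"] == pytest.approx(9.0, rel=0.05)


class TestDifferentialMap:
    def _balanced_pair(self, scale=1.0):
        g = GenomeSpec((("c", 4_000_000),), 1_000_000
                       )
        rng = np.random.default_rng(5)
        raw = np.triu(rng.poisson(20, (4, 4)).astype(float), 1)
        raw = raw + raw.T
        a = ice_normalize(ContactMap(g, {"c": raw}), tol=1e-8)
        b = ice_normalize(ContactMap(g, {"c": raw * scale}), tol=1e-8)
        return a, b

    def test_identical_maps_give_zero(self):
        a, _ = self._balanced_pair()
        diff = differential_map(a, a, 1_000_000)
        vals = diff.matrices["c"]
        np.testing.assert_allclose(vals[np.isfinite(vals)], 0.0, atol=1e-9)

    def test_swapping_arguments_negates(self):
        a, b = self._balanced_pair(scale=3.0)
        ab = differential_map(a, b, 1_000_000).matrices["c"]
        ba = differential_map(b, a, 1_000_000).matrices["c"]
        ok = np.isfinite(ab)
        np.testing.assert_allclose(ab[ok], -ba[ok], atol=1e-9)

    def test_doubling_gives_log2_of_two(self):
        g = GenomeSpec((("c", 4_000_000),), 1_000_000)
        rng = np.random.default_rng(6)
        raw = np.triu(rng.poisson(20, (4, 4)).astype(float), 1)
        raw = raw + raw.T
        a = ice_normalize(ContactMap(g, {"c": raw}), tol=1e-8)
        b = a.copy()
        for c in b.matrices:
            b.matrices[c] = b.matrices[c] * 2
        diff = differential_map(a, b, 1_000_000).matrices["c"]
        ok = np.isfinite(diff)
        np.testing.assert_allclose(diff[ok], 1.0, atol=1e-9)

    def test_mismatched_genomes_rejected(self):
        a, _ = self._balanced_pair()
        g2 = GenomeSpec((("c", 5_000_000),), 1_000_000)
        other = ContactMap.zeros(g2)
        other.weights = np.ones(g2.n_bins)
        with pytest.raises(ValueError):
            differential_map(a, other)
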