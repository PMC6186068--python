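"""Contact binning, ICE balancing and distance normalization."""

import numpy as np
import pandas as pd
import pytest

from chromaforge import genome_tracks as gt
from chromaforge import hic_maps as hm


@pytest.fixture
def bins30():
    return gt.make_bins(pd.DataFrame({"chrom": ["c"], "length": [30_000]}), 10_000)


def ipf_2x2_oracle(mat, n_iter=200):
    """Iterative proportional fitting by direct looping on a tiny matrix."""
    work = mat.astype(float).copy()
    for _ in range(n_iter):
        rs = work.sum(axis=1)
        d = rs / rs.mean()
        work = work / np.outer(d, d)
    return work


class TestBuildContactMatrix:
    def test_single_pair_symmetric(self, bins30):
        raw = hm.build_contact_matrix([("c", 5_000, "c", 25_000, "p1")], bins30)
        m = raw.matrices["c"]
        assert m[0, 2] == 1 and m[2, 0] == 1 and m.sum() == 2

    def test_dedupe_counts_unique_pair_ids_once(self, bins30):
        pairs = [("c", 5_000, "c", 25_000, "p1"), ("c", 5_100, "c", 25_100, "p1")]
        with_dedupe = hm.build_contact_matrix(pairs, bins30, dedupe=True)
        without = hm.build_contact_matrix(pairs, bins30, dedupe=False)
        assert with_dedupe.matrices["c"][0, 2] == 1
        assert without.matrices["c"][0, 2] == 2

    def test_same_bin_pairs_accumulate_on_diagonal(self, bins30):
        pairs = [("c", 11_000, "c", 12_000, f"p{k}") for k in range(3)]
        raw = hm.build_contact_matrix(pairs, bins30)
        assert raw.matrices["c"][1, 1] == 3

    def test_inter_chromosomal_dropped_and_out_of_bounds_warned(self, toy_bins):
        pairs = [
            ("chr1", 5_000, "chr2", 5_000, "a"),
            ("chr1", 500_000, "chr1", 5_000, "b"),
            ("chr1", 5_000, "chr1", 15_000, "c"),
        ]
        with pytest.warns(UserWarning, match="skipped 1"):
            raw = hm.build_contact_matrix(pairs, toy_bins)
        assert raw.matrices["chr1"].sum() == 2


class TestIceNormalize:
    def test_balanced_matrix_unchanged_up_to_scale(self):
        raw = hm.RawContactMap(["c"], {"c": np.array([[0.0, 4.0], [4.0, 0.0]])})
        out, biases = hm.ice_normalize(raw)
        ratio = out.matrices["c"][0, 1] / 4.0
        np.testing.assert_allclose(out.matrices["c"], ratio * raw.matrices["c"])

    def test_prescaled_row_matches_ipf_oracle(self):
        base = np.array([[0.0, 2.0], [2.0, 0.0]])
        scale = np.diag([3.0, 1.0])
        skewed = scale @ base @ scale  # row 0 inflated x3 on both axes
        raw = hm.RawContactMap(["c"], {"c": skewed})
        out, biases = hm.ice_normalize(raw, tol=1e-12, max_iter=500)
        oracle = ipf_2x2_oracle(skewed)
        np.testing.assert_allclose(out.matrices["c"], oracle, rtol=1e-8)
        rs = out.matrices["c"].sum(axis=1)
        assert np.ptp(rs) / rs.mean() < 1e-10

    def test_row_sums_equalized_on_random_matrix(self, rng):
        a = rng.uniform(0.5, 2.0, (5, 5))
        mat = a + a.T
        raw = hm.RawContactMap(["c"], {"c": mat})
        out, _ = hm.ice_normalize(raw, tol=1e-7)
        rs = out.matrices["c"].sum(axis=1)
        assert np.max(np.abs(rs - rs.mean())) / rs.mean() < 1e-5
        np.testing.assert_allclose(out.matrices["c"], out.matrices["c"].T)

    def test_idempotent_up_to_tol(self, rng):
        a = rng.uniform(0.5, 2.0, (6, 6))
        raw = hm.RawContactMap(["c"], {"c": a + a.T})
        once, _ = hm.ice_normalize(raw, tol=1e-10, max_iter=1000)
        twice, _ = hm.ice_normalize(once, tol=1e-10, max_iter=1000)
        np.testing.assert_allclose(twice.matrices["c"], once.matrices["c"], rtol=1e-8)

    def test_all_zero_matrix_rejected(self):
        raw = hm.RawContactMap(["c"], {"c": np.zeros((3, 3))})
        with pytest.raises(ValueError, match="all-zero"):
            hm.ice_normalize(raw)

    def test_zero_marginal_bins_masked(self):
        mat = np.array([[0.0, 2.0, 0.0], [2.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        raw = hm.RawContactMap(["c"], {"c": mat})
        out, _ = hm.ice_normalize(raw)
        assert not out.masks["c"][2]
        assert (out.matrices["c"][2] == 0).all()


class TestDistanceNormalize:
    def test_constant_diagonals_become_ones(self):
        n = 6
        mat = np.zeros((n, n))
        for d in range(n):
            mat += np.eye(n, k=d) * (n - d) + (np.eye(n, k=-d) * (n - d) if d else 0)
        raw = hm.RawContactMap(["c"], {"c": mat})
        norm = hm.distance_normalize(raw)
        out = norm.matrices["c"]
        np.testing.assert_allclose(out, np.ones((n, n)), atol=1e-12)

    def test_mean_per_diagonal_is_one(self, rng):
        a = rng.uniform(0.1, 3.0, (8, 8))
        raw = hm.RawContactMap(["c"], {"c": a + a.T})
        norm = hm.distance_normalize(raw)
        out = norm.matrices["c"]
        for d in range(8):
            assert np.diagonal(out, d).mean() == pytest.approx(1.0, abs=1e-10)

    def test_two_entry_diagonal_splits_around_mean(self):
        mat = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 3.0], [0.0, 3.0, 1.0]])
        # force no masking: all marginals nonzero; diagonal d=1 entries {1, 3}
        raw = hm.RawContactMap(["c"], {"c": mat})
        norm = hm.distance_normalize(raw)
        out = norm.matrices["c"]
        assert out[0, 1] == pytest.approx(0.5)
        assert out[1, 2] == pytest.approx(1.5)

    def test_idempotent(self, rng):
        a = rng.uniform(0.1, 3.0, (7, 7))
        raw = hm.RawContactMap(["c"], {"c": a + a.T})
        once = hm.distance_normalize(raw)
        again = hm.distance_normalize(
            hm.RawContactMap(["c"], {"c": once.matrices["c"]}, {"c": once.masks["c"]})
        )
        np.testing.assert_allclose(again.matrices["c"], once.matrices["c"], atol=1e-12)

    def test_masked_bin_excluded_from_expected_and_output(self):
        a = np.ones((4, 4))
        a[2, :] = 0
        a[:, 2] = 0
        mask = np.array([True, True, False, True])
        raw = hm.RawContactMap(["c"], {"c": a}, {"c": mask})
        norm = hm.distance_normalize(raw)
        assert (norm.matrices["c"][2] == 0).all()
        for d in range(1, 4):
            diag = np.diagonal(norm.matrices["c"], d)
            dm = np.diagonal(np.outer(mask, mask), d)
            if dm.any():
                assert diag[dm].mean() == pytest.approx(1.0, abs=1e-10)

    def test_pooled_expected_spans_chromosomes(self):
        m1 = np.full((3, 3), 2.0)
        m2 = np.full((3, 3), 4.0)
        raw = hm.RawContactMap(["a", "b"], {"a": m1, "b": m2})
        norm = hm.distance_normalize(raw, expected_mode="pooled")
        # pooled expected is 3.0 at every distance
        np.testing.assert_allclose(norm.matrices["a"], m1 / 3.0)
        np.testing.assert_allclose(norm.matrices["b"], m2 / 3.0)
        per = hm.distance_normalize(raw, expected_mode="per-chrom")
        np.testing.assert_allclose(per.matrices["a"], np.ones((3, 3)))
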