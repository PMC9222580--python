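"""Constrained clustering, S_Dbw selection, boundary tools."""

import numpy as np
import pytest

from schicembed.hic_io import GenomeBins
from schicembed.tads import (
    Dendrogram,
    TadPartition,
    boundary_profile,
    boundary_vector,
    coniss_cluster,
    default_k_range,
    dissimilarity_from_embedding,
    overlap_coefficient,
    s_dbw,
    select_k,
)


def brute_coniss_merge_sequence(d):
    """Greedy adjacent-merge search recomputing every cost from scratch."""
    n = d.shape[0]
    clusters = [[i] for i in range(n)]

    def ess(members):
        members = np.asarray(members)
        sub = d[np.ix_(members, members)]
        return sub.sum() / (2 * len(members))

    boundaries = []
    while len(clusters) > 1:
        costs = [
            ess(clusters[a] + clusters[a + 1]) - ess(clusters[a]) - ess(clusters[a + 1])
            for a in range(len(clusters) - 1)
        ]
        a = int(np.argmin(costs))
        boundaries.append(clusters[a][-1])
        clusters[a] = clusters[a] + clusters.pop(a + 1)
    return boundaries


class TestDissimilarity:
    def test_identical_rows_zero(self):
        z = np.tile([1.0, 2.0, 3.0], (4, 1))
        np.testing.assert_array_equal(dissimilarity_from_embedding(z), np.zeros((4, 4)))

    def test_one_dimensional_gap(self):
        d = dissimilarity_from_embedding(np.array([[0.0], [2.0]]))
        assert d[0, 1] == 4.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=(6, 3))
        d = dissimilarity_from_embedding(z)
        for i in range(6):
            for j in range(6):
                assert d[i, j] == pytest.approx(
                    np.sum((z[i] - z[j]) ** 2), abs=1e-12
                )


class TestConiss:
    def test_two_tight_pairs(self):
        z = np.array([[0.0], [0.1], [10.0], [10.1]])
        dendro = coniss_cluster(dissimilarity_from_embedding(z))
        # first two merges join {0,1} and {2,3}; the last joins the pairs
        assert set(dendro.merge_boundaries[:2]) == {0, 2}
        assert dendro.merge_boundaries[-1] == 1

    def test_n2_single_merge(self):
        dendro = coniss_cluster(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert dendro.merge_boundaries == [0]

    def test_equally_spaced_leftmost_tiebreak(self):
        z = np.arange(5.0)[:, None]
        dendro = coniss_cluster(dissimilarity_from_embedding(z))
        assert dendro.merge_boundaries[0] == 0  # leftmost of the tied merges

    def test_cumulative_heights_nondecreasing(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(12, 2))
        dendro = coniss_cluster(dissimilarity_from_embedding(z))
        assert np.all(np.diff(dendro.heights) >= -1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        z = rng.normal(size=(n, 2))
        d = dissimilarity_from_embedding(z)
        dendro = coniss_cluster(d)
        assert dendro.merge_boundaries == brute_coniss_merge_sequence(d)

    def test_cut_contiguity(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(10, 2))
        dendro = coniss_cluster(dissimilarity_from_embedding(z))
        for k in range(1, 11):
            part = dendro.cut(k)
            assert len(part.clusters) == k
            # TadPartition validates contiguity/exhaustiveness on build

    def test_merge_cost_of_singletons_is_half_dissimilarity(self):
        d = np.array([[0.0, 6.0], [6.0, 0.0]])
        dendro = coniss_cluster(d)
        assert dendro.increments[0] == pytest.approx(3.0)


class TestSDbw:
    def test_true_split_beats_arbitrary_halving(self):
        rng = np.random.default_rng(12)
        blob1 = rng.normal(size=(30, 2)) * 0.3
        blob2 = rng.normal(size=(30, 2)) * 0.3 + 10.0
        x = np.vstack([blob1, blob2])
        true_labels = np.repeat([0, 1], 30)
        halved = np.tile([0, 1], 30)  # splits each blob arbitrarily in half
        assert s_dbw(x, true_labels) < s_dbw(x, halved)

    def test_zero_variance_clusters_scat_zero(self):
        x = np.vstack([np.zeros((5, 2)), np.ones((5, 2)) * 9])
        labels = np.repeat([0, 1], 5)
        assert s_dbw(x, labels) == 0.0

    def test_singletons_defined_and_finite(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 2))
        val = s_dbw(x, np.arange(6))
        assert np.isfinite(val)

    def test_fewer_than_two_clusters_rejected(self):
        with pytest.raises(ValueError):
            s_dbw(np.zeros((4, 2)), np.zeros(4, dtype=int))


class TestSelectK:
    def test_recovers_five_blocks(self):
        rng = np.random.default_rng(21)
        lengths = [12, 8, 15, 10, 9]
        centers = rng.normal(size=(5, 6)) * 4
        z = np.vstack([
            centers[i] + 0.25 * rng.normal(size=(l, 6)) for i, l in enumerate(lengths)
        ])
        dendro = coniss_cluster(dissimilarity_from_embedding(z))
        part = select_k(dendro, z)
        assert len(part.clusters) == 5
        starts = [c[0] for c in part.clusters]
        assert starts == [0, 12, 20, 35, 45]

    def test_n2_returns_singletons(self):
        z = np.array([[0.0, 0.0], [1.0, 1.0]])
        dendro = coniss_cluster(dissimilarity_from_embedding(z))
        part = select_k(dendro, z, k_range=[2])
        assert part.clusters == [(0, 0), (1, 1)]

    def test_constant_embedding_ties_to_min_k(self):
        z = np.ones((9, 3))
        dendro = coniss_cluster(dissimilarity_from_embedding(z))
        part = select_k(dendro, z, k_range=range(2, 6))
        assert len(part.clusters) == 2

    def test_empty_k_range_rejected(self):
        z = np.random.default_rng(0).normal(size=(6, 2))
        dendro = coniss_cluster(dissimilarity_from_embedding(z))
        with pytest.raises(ValueError, match="empty"):
            select_k(dendro, z, k_range=[])

    def test_default_k_range_bounds(self):
        assert list(default_k_range(9)) == [2, 3]
        assert default_k_range(300).stop == 101


class TestOverlapCoefficient:
    def test_identical_sets(self):
        assert overlap_coefficient([3, 7, 9], [3, 7, 9]) == 1.0

    def test_disjoint_far_sets(self):
        assert overlap_coefficient([0, 10], [5, 20], tol_bins=1) == 0.0

    def test_tolerant_matching(self):
        assert overlap_coefficient([10, 20, 30], [11, 29], tol_bins=1) == 1.0

    def test_one_to_one_matching(self):
        # both elements of the smaller set cannot match the same boundary
        assert overlap_coefficient([10, 11], [10, 50], tol_bins=1) == 0.5

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_coefficient([], [1, 2])

    @pytest.mark.parametrize("seed", range(4))
    def test_symmetric_for_equal_sizes_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        b1 = rng.choice(100, size=8, replace=False)
        b2 = rng.choice(100, size=8, replace=False)
        v1 = overlap_coefficient(b1, b2)
        v2 = overlap_coefficient(b2, b1)
        assert v1 == v2
        assert 0.0 <= v1 <= 1.0


class TestBoundaryProfile:
    def make_partition(self, clusters, n_bins, res=50_000):
        bins = GenomeBins("chr1", res, n_bins)
        return TadPartition(clusters=clusters, n_bins=n_bins, bins=bins)

    def test_constant_track(self):
        part = self.make_partition([(0, 9), (10, 19)], 20)
        track = np.full(20 * 5, 3.5)  # 10 kb track under 50 kb bins
        prof = boundary_profile(part, track, flank_bp=200_000, bin_bp=10_000)
        assert len(prof) == 41
        np.testing.assert_allclose(prof[np.isfinite(prof)], 3.5)

    def test_dip_at_boundaries_recovered(self):
        part = self.make_partition([(0, 9), (10, 19)], 20)
        track = np.ones(100)
        for b in part.boundaries:
            track[b * 5] -= 0.5
        prof = boundary_profile(part, track, flank_bp=200_000, bin_bp=10_000)
        assert np.nanargmin(prof) == 20  # centre of the 41-bin window

    def test_two_boundary_hand_average(self):
        rng = np.random.default_rng(5)
        track = rng.random(400)
        part = self.make_partition([(0, 19), (20, 39)], 40, res=10_000)
        # boundaries at bins 0, 19, 20, 39 -> fine centres equal bin index
        prof = boundary_profile(part, track, flank_bp=50_000, bin_bp=10_000)
        width = 11
        acc = np.zeros(width)
        cnt = np.zeros(width)
        for b in [0, 19, 20, 39]:
            for off in range(-5, 6):
                idx = b + off
                if 0 <= idx < 400:
                    acc[off + 5] += track[idx]
                    cnt[off + 5] += 1
        np.testing.assert_allclose(prof, acc / cnt)

    def test_default_window_is_81_bins(self):
        part = self.make_partition([(0, 49), (50, 99)], 100)
        prof = boundary_profile(part, np.ones(500))
        assert len(prof) == 81


class TestBoundaryVector:
    def test_single_tad(self):
        part = TadPartition(clusters=[(0, 9)], n_bins=10)
        v = boundary_vector(part)
        expected = np.zeros(10)
        expected[[0, 9]] = 1
        np.testing.assert_array_equal(v, expected)

    def test_k_tads_endpoints(self):
        part = TadPartition(clusters=[(0, 2), (3, 6), (7, 9)], n_bins=10)
        v = boundary_vector(part)
        assert set(np.flatnonzero(v)) == {0, 2, 3, 6, 7, 9}

    def test_round_trip(self):
        part = TadPartition(clusters=[(0, 4), (5, 9)], n_bins=10)
        v = boundary_vector(part)
        np.testing.assert_array_equal(np.flatnonzero(v), part.boundaries)


class TestTadPartitionValidation:
    def test_gap_rejected(self):
        with pytest.raises(ValueError):
            TadPartition(clusters=[(0, 3), (5, 9)], n_bins=10)

    def test_incomplete_cover_rejected(self):
        with pytest.raises(ValueError):
            TadPartition(clusters=[(0, 3)], n_bins=10)

    def test_labels(self):
        part = TadPartition(clusters=[(0, 1), (2, 4)], n_bins=5)
        np.testing.assert_array_equal(part.labels(), [0, 0, 1, 1, 1])
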