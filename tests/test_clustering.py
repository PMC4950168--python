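import numpy as np
import pytest

from landclust import ClusteringConfig, decompose, find_local_maxima, grow_cluster

from conftest import make_landscape, random_landscape
import reference as ref


def pyramid(shape, center, height, step=1.0):
    """A hill decaying by ``step`` per Chebyshev ring, clipped at 0.

    Constant downhill slope along every outward path, so the slope-
    reversal rule never triggers inside the support: the whole support
    becomes exactly one cluster, and the zero floor (a plateau, hence
    without strict local maxima) stays unclaimed.
    """
    idx = np.indices(shape, dtype=float)
    cheb = np.max(np.abs(np.stack([idx[a] - center[a] for a in range(len(shape))])), axis=0)
    return np.clip(height - step * cheb, 0.0, None)


class TestLocalMaxima:
    def test_constant_landscape_has_no_maxima(self):
        ls = make_landscape(np.ones((4, 4, 2)))
        assert find_local_maxima(ls).shape == (0, 3)

    def test_isolated_voxel_is_a_maximum(self):
        mask = np.zeros((3, 3, 1), bool)
        mask[1, 1, 0] = True
        ls = make_landscape(np.full((3, 3, 1), 2.0), mask=mask)
        assert [tuple(v) for v in find_local_maxima(ls)] == [(1, 1, 0)]

    def test_two_bumps_found_in_height_order(self):
        vals = np.maximum(
            pyramid((7, 7, 1), (1, 1, 0), 3.5), pyramid((7, 7, 1), (5, 5, 0), 5.5)
        )
        ls = make_landscape(vals)
        got = [tuple(v) for v in find_local_maxima(ls)]
        assert got == [(5, 5, 0), (1, 1, 0)]

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_agrees_with_bruteforce(self, rng, connectivity):
        for _ in range(25):
            ls = random_landscape(rng, shape=(6, 5, 3))
            cfg = ClusteringConfig(connectivity=connectivity)
            got = [tuple(v) for v in find_local_maxima(ls, config=cfg)]
            want = [tuple(v) for v in ref.ref_local_maxima(ls.values, ls.mask, connectivity)]
            assert got == want


class TestGrowCluster:
    def line(self, profile):
        return make_landscape(np.asarray(profile, float))

    def test_symmetric_peak_stops_at_slope_reversal(self):
        # slopes from 5: -3, then -1 > -3 -> the 1s are boundary non-members
        ls = self.line([1, 2, 5, 2, 1])
        c = grow_cluster(ls, (2, 0, 0))
        assert sorted(map(tuple, c.voxels)) == [(1, 0, 0), (2, 0, 0), (3, 0, 0)]
        assert c.score == pytest.approx(9.0)
        assert c.peak_value == pytest.approx(5.0)

    def test_constant_slope_never_stops(self):
        ls = self.line([5, 4, 3, 2, 1])
        c = grow_cluster(ls, (0, 0, 0))
        assert c.size == 5  # equal slope continues growth ("more positive" is strict)

    def test_concave_then_convex_flank_excludes_tail(self):
        # slopes -1, -2, -3, then -1 > -3: the last voxel is excluded
        ls = self.line([10, 9, 7, 4, 3])
        c = grow_cluster(ls, (0, 0, 0))
        assert sorted(map(tuple, c.voxels)) == [(i, 0, 0) for i in range(4)]

    def test_rejects_non_maximum_seed(self):
        ls = self.line([1, 2, 5, 2, 1])
        with pytest.raises(ValueError):
            grow_cluster(ls, (1, 0, 0))

    def test_rejects_unavailable_seed(self):
        ls = self.line([1, 2, 5, 2, 1])
        avail = np.ones((5, 1, 1), bool)
        avail[2] = False
        with pytest.raises(ValueError):
            grow_cluster(ls, (2, 0, 0), available=avail)

    def test_agrees_with_path_oracle(self, rng):
        cfg = ClusteringConfig()
        for _ in range(25):
            ls = random_landscape(rng, shape=(6, 6, 3))
            peaks = find_local_maxima(ls)
            peak = tuple(peaks[0])
            got = set(map(tuple, grow_cluster(ls, peak).voxels))
            want = ref.ref_grow(ls.values, ls.mask.copy(), peak)
            assert got == want

    def test_normalized_slope_option_diverges_on_anisotropic_steps(self, rng):
        # with per-mm slopes, diagonal steps are damped; membership may differ
        ls = random_landscape(rng, shape=(6, 6, 3))
        peak = tuple(find_local_maxima(ls)[0])
        got = set(
            map(tuple, grow_cluster(ls, peak, config=ClusteringConfig(normalize_slope=True)).voxels)
        )
        want = ref.ref_grow(ls.values, ls.mask.copy(), peak, normalize=True)
        assert got == want


class TestDecompose:
    def test_single_bump_single_cluster(self):
        ls = make_landscape(pyramid((9, 9, 1), (4, 4, 0), 3.5))
        cs = decompose(ls)
        assert cs.n_clusters == 1
        assert cs.peak_coords(1) == (4, 4, 0)
        # support = Chebyshev ball of radius 3; the zero floor is unclaimed
        assert cs.sizes[0] == 49
        assert cs.scores[0] == pytest.approx(3.5 + 8 * 2.5 + 16 * 1.5 + 24 * 0.5)

    def test_two_identical_bumps_tie_broken_by_linear_index(self):
        vals = np.maximum(
            pyramid((13, 13, 1), (3, 3, 0), 2.5), pyramid((13, 13, 1), (9, 9, 0), 2.5)
        )
        cs = decompose(make_landscape(vals))
        assert cs.n_clusters == 2
        assert cs.peak_coords(1) == (3, 3, 0)  # equal peaks: lower linear index first
        assert cs.peak_coords(2) == (9, 9, 0)
        assert cs.scores[0] == pytest.approx(cs.scores[1], rel=1e-9)

    def test_disjoint_and_peak_dominant(self, rng):
        for _ in range(20):
            ls = random_landscape(rng, shape=(7, 7, 3))
            cs = decompose(ls)
            # disjointness: labels partition the claimed voxels
            assert cs.sizes.sum() == (cs.label_grid > 0).sum()
            for k in range(1, cs.n_clusters + 1):
                vox = cs.cluster_voxels(k)
                assert ls.values[cs.peak_coords(k)] == ls.values[tuple(vox.T)].max()
                assert cs.scores[k - 1] == pytest.approx(ls.values[tuple(vox.T)].sum())

    def test_agrees_with_naive_reference(self, rng):
        for _ in range(10):
            ls = random_landscape(rng, shape=(7, 7, 3))
            cs = decompose(ls)
            want = ref.ref_decompose(ls.values, ls.mask.copy())
            assert cs.n_clusters == len(want)
            for k, (peak, members) in enumerate(want, start=1):
                assert cs.peak_coords(k) == peak
                assert set(map(tuple, cs.cluster_voxels(k))) == members

    def test_deterministic(self, rng):
        ls = random_landscape(rng, shape=(8, 8, 4))
        a, b = decompose(ls), decompose(ls)
        assert np.array_equal(a.label_grid, b.label_grid)
        assert np.array_equal(a.peak_lin, b.peak_lin)

    def test_pre_threshold_below_floor_changes_nothing(self, rng):
        ls = random_landscape(rng, shape=(7, 6, 3))
        ls.values += 2.0  # every value > -log10(0.99) ~ 0.004
        free = decompose(ls)
        thr = decompose(ls, ClusteringConfig(pre_threshold=0.99))
        assert np.array_equal(free.label_grid, thr.label_grid)

    def test_pre_threshold_excludes_low_voxels(self):
        vals = pyramid((9, 9, 1), (4, 4, 0), 3.5)
        cs = decompose(make_landscape(vals), ClusteringConfig(pre_threshold=0.05))
        thr = -np.log10(0.05)
        claimed = cs.label_grid > 0
        assert claimed.any()
        assert np.all(vals[claimed] > thr)

    def test_empty_mask_yields_empty_clusterset(self):
        ls = make_landscape(np.zeros((3, 3, 3)), mask=np.zeros((3, 3, 3), bool))
        cs = decompose(ls)
        assert cs.n_clusters == 0 and len(cs.clusters) == 0
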