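import math

import numpy as np
import pytest

from landclust import (
    ClusteringConfig,
    ClusterSet,
    CombinationMetrics,
    combine_all,
    compute_metrics,
    decompose,
    should_combine,
)

from conftest import make_landscape, random_landscape
from test_clustering import pyramid
import reference as ref


def manual_clusterset(values, labels, peak_lins):
    """Build a ClusterSet directly from a hand-written label grid."""
    ls = make_landscape(values)
    labels = np.asarray(labels, dtype=np.int32)
    while labels.ndim < 3:
        labels = labels[..., None]
    return ClusterSet(labels, ls, ClusteringConfig(), np.asarray(peak_lins, dtype=np.int64))


class TestComputeMetrics:
    def test_fully_surrounded_cluster_has_proportion_one(self):
        # cluster 2 = single center voxel, cluster 1 = the surrounding ring
        values = np.full((3, 3), 1.0)
        values[1, 1] = 2.0
        values[0, 0] = 5.0
        labels = np.ones((3, 3), int)
        labels[1, 1] = 2
        cs = manual_clusterset(values, labels, [0, 4])  # peaks: (0,0) and (1,1)
        m = compute_metrics(cs, lower_label=2, higher_label=1)
        assert m.proportion_connected == 1.0
        assert should_combine(m)

    def test_single_contact_voxel_out_of_ten(self):
        # cluster 1: a 10-voxel row flanked by unclaimed ground (all edge);
        # cluster 2: one higher voxel diagonally touching one end only
        values = np.ones((11, 3))
        values[0, 1] = 2.0  # peak of cluster 1
        values[10, 1] = 5.0  # cluster 2
        labels = np.zeros((11, 3), int)
        labels[0:10, 1] = 1
        labels[10, 1] = 2
        cs = manual_clusterset(values, labels, [0 * 3 + 1, 10 * 3 + 1])
        m = compute_metrics(cs, lower_label=1, higher_label=2)
        assert m.proportion_connected == pytest.approx(0.1)
        assert m.peaks_difference == pytest.approx(3.0)
        assert m.smaller_peak_to_connecting_edge == pytest.approx(1.0)

    def test_not_adjacent_signals_no_decision(self):
        values = np.ones((5, 1))
        values[0, 0], values[4, 0] = 3.0, 2.0
        labels = np.zeros((5, 1), int)
        labels[0, 0], labels[4, 0] = 1, 2
        cs = manual_clusterset(values, labels, [0, 4])
        m = compute_metrics(cs, lower_label=2, higher_label=1)
        assert m.proportion_connected == 0.0
        assert math.isnan(m.smaller_peak_to_connecting_edge)
        assert not should_combine(m)

    def test_hand_built_two_bump_grid(self):
        # two touching pyramid supports; metrics measured on the lower one
        vals = np.maximum(
            pyramid((8, 8, 1), (2, 2, 0), 2.5), pyramid((8, 8, 1), (5, 5, 0), 3.5)
        )
        cs = decompose(make_landscape(vals))
        assert cs.n_clusters == 2
        m = compute_metrics(cs, lower_label=2, higher_label=1)
        # hand counts: the lower support's claimed voxels that border the
        # higher cluster, over all its edge voxels
        lower_vox = set(map(tuple, cs.cluster_voxels(2)))
        higher_vox = set(map(tuple, cs.cluster_voxels(1)))
        edge = connecting = 0
        conn_vals = []
        for v in lower_vox:
            nbs = [
                (v[0] + dx, v[1] + dy, 0)
                for dx in (-1, 0, 1)
                for dy in (-1, 0, 1)
                if (dx, dy) != (0, 0)
                and 0 <= v[0] + dx < 8
                and 0 <= v[1] + dy < 8
            ]
            if any(w not in lower_vox for w in nbs):
                edge += 1
                if any(w in higher_vox for w in nbs):
                    connecting += 1
                    conn_vals.append(vals[v])
        assert m.proportion_connected == pytest.approx(connecting / edge)
        assert m.smaller_peak_to_connecting_edge == pytest.approx(
            cs.peak_values[1] - np.mean(conn_vals)
        )
        assert m.peaks_difference == pytest.approx(1.0)


class TestShouldCombine:
    @pytest.mark.parametrize(
        "pc, pd, sp, expected",
        [
            (1.0, 0.5, 2.0, True),  # fully surrounded: RHS = 0
            (0.5, 1.0, 3.0, False),  # 0.25 >= 0.5 fails
            (0.1, 2.0, 0.0, True),  # lower peak at flank level: LHS = 1
            (0.2, 2.0, 3.0, False),  # 0.4 >= 0.8 fails
            (0.9, 1.0, 4.0, True),  # 0.2 >= 0.1 holds
            (0.5, 0.0, 0.0, True),  # degenerate 0/0: zero separation
        ],
    )
    def test_inequality_truth_table(self, pc, pd, sp, expected):
        assert should_combine(CombinationMetrics(pc, pd, sp)) is expected

    def test_no_contact_is_no_decision(self):
        assert not should_combine(CombinationMetrics(0.0, 1.0, 1.0))


class TestCombineAll:
    def test_bump_on_flank_is_absorbed(self):
        # a dominant hill with one secondary local maximum on its flank
        vals = pyramid((9, 9, 1), (4, 4, 0), 5.0)
        vals[2, 2, 0] = 4.2  # raise one ring-2 voxel into a local max
        cs = decompose(make_landscape(vals))
        assert cs.n_clusters >= 2
        merged = combine_all(cs)
        assert merged.n_clusters == 1
        assert merged.scores[0] == pytest.approx(cs.scores.sum())

    def test_separated_bumps_with_minimal_contact_stay_apart(self):
        vals = np.maximum(
            pyramid((10, 10, 1), (2, 2, 0), 2.5), pyramid((10, 10, 1), (7, 7, 0), 2.6)
        )
        cs = decompose(make_landscape(vals))
        assert cs.n_clusters == 2
        m = compute_metrics(cs, lower_label=2, higher_label=1)
        assert 0 < m.proportion_connected < 0.2
        assert not should_combine(m)
        merged = combine_all(cs)
        assert merged.n_clusters == 2

    def test_idempotent(self, rng):
        for _ in range(10):
            ls = random_landscape(rng, shape=(7, 7, 3))
            once = combine_all(decompose(ls))
            twice = combine_all(once)
            assert np.array_equal(once.label_grid, twice.label_grid)

    def test_fixed_point_no_pair_still_qualifies(self, rng):
        for _ in range(5):
            ls = random_landscape(rng, shape=(7, 6, 3))
            merged = combine_all(decompose(ls))
            ids = np.arange(1, merged.n_clusters + 1)
            order = ids[np.lexsort((ids, merged.peak_values))]
            rank = {int(k): i for i, k in enumerate(order)}
            for a in ids:
                for b in ids:
                    if a == b:
                        continue
                    lo, hi = (a, b) if (
                        (merged.peak_values[a - 1], rank[int(a)])
                        < (merged.peak_values[b - 1], rank[int(b)])
                    ) else (b, a)
                    if lo != a:
                        continue
                    m = compute_metrics(merged, int(lo), int(hi))
                    if m.proportion_connected > 0:
                        assert not should_combine(m)

    def test_matches_pure_python_reference(self, rng):
        for _ in range(10):
            ls = random_landscape(rng, shape=(6, 6, 3))
            cs = decompose(ls)
            clusters = [
                (cs.peak_coords(k), set(map(tuple, cs.cluster_voxels(k))))
                for k in range(1, cs.n_clusters + 1)
            ]
            want = ref.ref_combine(ls.values, ls.mask, clusters)
            merged = combine_all(cs)
            got = {
                frozenset(map(tuple, merged.cluster_voxels(k)))
                for k in range(1, merged.n_clusters + 1)
            }
            assert got == {frozenset(m) for m in want.values()}

    def test_score_additivity(self, rng):
        ls = random_landscape(rng, shape=(8, 7, 3))
        cs = decompose(ls)
        merged = combine_all(cs)
        assert merged.scores.sum() == pytest.approx(cs.scores.sum())
        assert merged.sizes.sum() == cs.sizes.sum()
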