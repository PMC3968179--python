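import numpy as np
import pytest

from coupledicd import group as g
from coupledicd import metrics as m
from coupledicd.volume_io import BrainMask, ScalarMap, scatter_map
from coupledicd.synthetic import default_mask

from conftest import make_ts, pearson_brute


def maps_from_matrix(data, mask):
    """One ScalarMap per row of an n_subjects x V matrix."""
    return g.GroupMaps(maps=[scatter_map(row, mask) for row in data])


class TestTopPercent:
    def test_exact_percentile_count(self, rng):
        mask = default_mask(100)
        base = rng.permutation(100).astype(float)   # distinct effect ranks
        data = base[None, :] + rng.normal(0, 1e-3, (5, 100))
        out = g.top_percent(maps_from_matrix(data, mask), percent=15,
                            cluster_min=1)
        assert out.masked_values().sum() == 15

    def test_small_component_removed(self, rng):
        mask = BrainMask(labels=np.ones((7, 7, 7), dtype=bool))
        v = 343
        effect = np.zeros(v)
        grid = np.zeros((7, 7, 7), dtype=bool)
        grid[:7, :7, :1] = True          # a 49-voxel slab component
        effect[np.flatnonzero(grid.ravel())] = 10.0
        data = effect[None, :] + rng.normal(0, 1e-3, (6, v)) + 1.0
        # percent chosen so the nearest-rank cut selects exactly the slab
        out = g.top_percent(maps_from_matrix(data, mask),
                            percent=14, cluster_min=50)
        assert out.masked_values().sum() == 0    # 49 < 50 cluster floor

    def test_cluster_at_threshold_survives(self, rng):
        mask = BrainMask(labels=np.ones((7, 7, 7), dtype=bool))
        v = 343
        effect = np.zeros(v)
        grid = np.zeros((7, 7, 7), dtype=bool)
        grid[:5, :5, :2] = True          # 50-voxel block
        effect[np.flatnonzero(grid.ravel())] = 10.0
        data = effect[None, :] + rng.normal(0, 1e-3, (6, v)) + 1.0
        out = g.top_percent(maps_from_matrix(data, mask),
                            percent=14.5, cluster_min=50)
        assert out.masked_values().sum() == 50

    def test_constant_maps_warn_and_empty(self):
        mask = default_mask(60)
        data = np.ones((4, 60))
        with pytest.warns(UserWarning, match="zero-SD"):
            out = g.top_percent(maps_from_matrix(data, mask), cluster_min=1)
        assert out.masked_values().sum() == 0

    def test_selection_bound_before_clustering(self, rng):
        mask = default_mask(200)
        data = rng.normal(size=(8, 200))
        out = g.top_percent(maps_from_matrix(data, mask), percent=15,
                            cluster_min=1)
        assert out.masked_values().sum() <= np.ceil(0.15 * 200)

    def test_invariant_to_common_positive_scaling(self, rng):
        mask = default_mask(150)
        data = rng.normal(size=(6, 150)) + 2.0
        a = g.top_percent(maps_from_matrix(data, mask), cluster_min=1)
        b = g.top_percent(maps_from_matrix(3.7 * data, mask), cluster_min=1)
        assert np.array_equal(a.values, b.values)


class TestVoxelwiseTTest:
    def test_constant_offset_paired(self, rng):
        mask = default_mask(40)
        a = rng.normal(size=(6, 40))
        ga = maps_from_matrix(a, mask)
        gb = maps_from_matrix(a + 1.0, mask)
        tmap, pmap = g.voxelwise_ttest(ga, gb, paired=True)
        assert np.all(pmap.masked_values() < 1e-10)

    def test_zero_difference_degenerate_convention(self):
        mask = default_mask(1)
        a = maps_from_matrix(np.array([[1.0], [2.0], [3.0]]), mask)
        tmap, pmap = g.voxelwise_ttest(a, a, paired=True)
        assert tmap.masked_values()[0] == 0.0
        assert pmap.masked_values()[0] == 1.0

    def test_type_one_error_calibration(self, rng):
        mask = default_mask(1000)
        fracs = []
        for _ in range(20):
            ga = maps_from_matrix(rng.normal(size=(15, 1000)), mask)
            gb = maps_from_matrix(rng.normal(size=(15, 1000)), mask)
            _, pmap = g.voxelwise_ttest(ga, gb)
            fracs.append((pmap.masked_values() < 0.05).mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)

    def test_small_groups_rejected(self, rng):
        mask = default_mask(5)
        a = maps_from_matrix(rng.normal(size=(1, 5)), mask)
        b = maps_from_matrix(rng.normal(size=(3, 5)), mask)
        with pytest.raises(ValueError):
            g.voxelwise_ttest(a, b)


class TestFDR:
    def test_hand_computed_bh_example(self):
        reject = g.fdr_correct([0.001, 0.2, 0.9], q=0.05)
        assert reject.tolist() == [True, False, False]

    def test_all_ones_none_rejected(self):
        assert not g.fdr_correct(np.ones(10)).any()

    def test_all_zeros_all_rejected(self):
        assert g.fdr_correct(np.zeros(10)).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            g.fdr_correct([0.5, 1.5])


class TestMatrixConnectivity:
    def test_single_voxel_node_identity(self, rng):
        mask = default_mask(8, (2, 2, 2))
        ts = make_ts(rng.normal(size=(8, 40)), mask=mask)
        labels = np.arange(1, 9).reshape(2, 2, 2)
        atlas = g.ParcellationAtlas(labels=labels, n_nodes=8)
        courses = g.parcellate(ts, atlas)
        assert np.allclose(courses, ts.values)

    def test_two_identical_courses_average(self, rng):
        mask = default_mask(4, (4, 1, 1))
        x = rng.normal(size=40)
        ts = make_ts(np.vstack([x, x, rng.normal(size=(2, 40))]), mask=mask)
        labels = np.array([1, 1, 2, 2]).reshape(4, 1, 1)
        courses = g.parcellate(ts, g.ParcellationAtlas(labels, 2))
        assert np.allclose(courses[0], x)

    def test_parcellate_matches_bruteforce(self, rng):
        mask = default_mask(30, (30, 1, 1))
        ts = make_ts(rng.normal(size=(30, 50)), mask=mask)
        labels = (rng.integers(1, 6, size=30)).reshape(30, 1, 1)
        atlas = g.ParcellationAtlas(labels, 5)
        courses = g.parcellate(ts, atlas)
        flat = labels.ravel()
        for node in range(1, 6):
            rows = ts.values[flat == node]
            expected = sum(rows) / len(rows)
            assert np.max(np.abs(courses[node - 1] - expected)) < 1e-12

    def test_fisher_z_values(self, rng):
        courses = rng.normal(size=(2, 500))
        cm = g.connectivity_matrix(courses)
        r = np.corrcoef(courses)[0, 1]
        assert cm.z[0, 1] == pytest.approx(np.arctanh(r), abs=1e-12)
        assert np.isnan(cm.z[0, 0])
        # closed-form anchor: atanh(0.5) ~ 0.5493
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_perfect_correlation_clipped_with_warning(self, rng):
        base = rng.normal(size=100)
        with pytest.warns(UserWarning, match="clipped"):
            cm = g.connectivity_matrix(np.vstack([base, 2 * base + 1]))
        assert cm.z[0, 1] == pytest.approx(np.arctanh(g.FISHER_CLIP))

    def test_fisher_round_trip(self, rng):
        courses = rng.normal(size=(6, 200))
        cm = g.connectivity_matrix(courses)
        r = np.corrcoef(courses)
        iu = np.triu_indices(6, 1)
        assert np.max(np.abs(np.tanh(cm.z[iu]) - r[iu])) < 1e-12

    def test_symmetry(self, rng):
        cm = g.connectivity_matrix(rng.normal(size=(10, 80)))
        iu = np.triu_indices(10, 1)
        assert np.array_equal(cm.z[iu], cm.z.T[iu])


class TestEdgewise:
    def _matrices(self, rng, n, nodes=12, shift=None):
        out = []
        for _ in range(n):
            z = rng.normal(0, 0.2, size=(nodes, nodes))
            z = (z + z.T) / 2
            if shift is not None:
                i, j, s = shift
                z[i, j] += s
                z[j, i] += s
            np.fill_diagonal(z, np.nan)
            out.append(g.ConnectivityMatrix(z=z))
        return out

    def test_identical_groups_no_edges(self, rng):
        a = self._matrices(rng, 10)
        flags, counts = g.edgewise_ttest(a, a, paired=True)
        assert not flags.any()
        assert counts.sum() == 0

    def test_shifted_edge_detected(self, rng):
        detected = 0
        for rep in range(30):
            a = self._matrices(rng, 15)
            b = self._matrices(rng, 15, shift=(2, 7, 1.0))  # 5 pooled SD
            flags, _ = g.edgewise_ttest(a, b)
            detected += bool(flags[2, 7])
        assert detected >= 29

    def test_handshake_identity(self, rng):
        a = self._matrices(rng, 8)
        b = self._matrices(rng, 8, shift=(1, 3, 1.5))
        flags, counts = g.edgewise_ttest(a, b)
        assert counts.sum() == 2 * flags[np.triu_indices(12, 1)].sum()

    def test_size_mismatch_rejected(self, rng):
        a = self._matrices(rng, 3)
        b = self._matrices(rng, 3, nodes=10)
        with pytest.raises(ValueError, match="mismatch"):
            g.edgewise_ttest(a, b)


class TestSeedMap:
    def test_single_voxel_seed_matches_correlation_row(self, rng):
        mask = default_mask(20, (20, 1, 1))
        ts = make_ts(rng.normal(size=(20, 100)), mask=mask)
        labels = np.zeros((20, 1, 1), dtype=bool)
        labels[4] = True
        roi = g.SeedROI(mask=BrainMask(labels=labels), name="v4")
        out = g.seed_map(ts, roi).masked_values()
        r = m.correlation_row(ts, 4)
        expected = np.arctanh(np.clip(r, -g.FISHER_CLIP, g.FISHER_CLIP))
        assert np.max(np.abs(np.delete(out, 4) - expected)) < 1e-10
        assert out[4] == pytest.approx(np.arctanh(g.FISHER_CLIP))

    def test_whole_mask_seed_on_identical_courses(self, rng):
        mask = default_mask(6, (6, 1, 1))
        base = rng.normal(size=50)
        ts = make_ts(np.tile(base, (6, 1)), mask=mask)
        roi = g.SeedROI(mask=BrainMask(labels=np.ones((6, 1, 1), bool)))
        out = g.seed_map(ts, roi).masked_values()
        assert np.all(out >= np.arctanh(g.FISHER_CLIP) - 1e-9)

    def test_matches_bruteforce_oracle(self, rng):
        mask = default_mask(25, (25, 1, 1))
        vals = rng.normal(size=(25, 60))
        ts = make_ts(vals, mask=mask)
        labels = np.zeros((25, 1, 1), dtype=bool)
        labels[[2, 5, 9]] = True
        out = g.seed_map(ts, g.SeedROI(mask=BrainMask(labels=labels)))
        course = (vals[2] + vals[5] + vals[9]) / 3
        for y in range(25):
            expected = np.arctanh(np.clip(pearson_brute(course, vals[y]),
                                          -g.FISHER_CLIP, g.FISHER_CLIP))
            assert out.masked_values()[y] == pytest.approx(expected,
                                                           abs=1e-10)

    def test_constant_seed_rejected(self, rng):
        mask = default_mask(5, (5, 1, 1))
        vals = rng.normal(size=(5, 30))
        vals[1] = 2.0
        labels = np.zeros((5, 1, 1), dtype=bool)
        labels[1] = True
        with pytest.raises(ValueError, match="constant"):
            g.seed_map(make_ts(vals, mask=mask),
                       g.SeedROI(mask=BrainMask(labels=labels)))


class TestPermutationClusters:
    def test_null_quantile_reasonable(self, rng):
        mask = default_mask(216, (6, 6, 6))
        a = maps_from_matrix(rng.normal(size=(8, 216)), mask)
        b = maps_from_matrix(rng.normal(size=(8, 216)), mask)
        sizes = g.permutation_max_cluster(a, b, paired=True, n_perm=50,
                                          seed=1)
        assert sizes.shape == (50,)
        assert sizes.min() >= 0
        # under the null, giant clusters are rare
        assert np.percentile(sizes, 95) < 216
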