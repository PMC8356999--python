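"""Feature preparation, fuzzy c-means, and the medial/lateral reduction."""

import numpy as np
import pytest

import dntopo as dt
from dntopo.microstructure import _membership_from_distances

from conftest import make_label_volume


def fm_from_values(values, grid=None, indices=None):
    values = np.asarray(values, dtype=float)
    n, f = values.shape
    if grid is None:
        grid = dt.default_grid(shape=(max(n, 2), 2, 2), voxel_mm=1.0)
    if indices is None:
        indices = np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])
    return dt.FeatureMatrix(
        grid=grid,
        voxel_indices=indices,
        feature_names=tuple(f"f{i}" for i in range(f)),
        values=values,
    )


class TestBuildFeatureMatrix:
    def test_rows_match_mask_and_carry_values(self, small_grid):
        mask = np.zeros(small_grid.shape, dtype=int)
        mask[2, 2, 2] = mask[3, 3, 3] = mask[4, 4, 4] = 1
        mask_vol = make_label_volume(small_grid, mask, {1: "DN"})
        metrics = {}
        for m, name in enumerate(dt.METRIC_NAMES):
            vals = np.zeros(small_grid.shape)
            vals[2, 2, 2] = 0.28 if name == "FA" else m + 1.0
            vals[3, 3, 3] = 1.2 if name == "MK" else m + 2.0
            vals[4, 4, 4] = m + 3.0
            metrics[name] = dt.ScalarVolume(grid=small_grid, values=vals)
        fm = dt.build_feature_matrix(metrics, mask_vol)
        assert fm.values.shape == (3, 7)
        assert fm.values[0, 0] == 0.28  # FA at the first mask voxel
        assert fm.values[1, 4] == 1.2  # MK at the second

    def test_missing_metric_rejected(self, small_grid):
        mask_vol = make_label_volume(
            small_grid, np.ones(small_grid.shape, dtype=int), {1: "DN"}
        )
        metrics = {
            n: dt.ScalarVolume(grid=small_grid, values=np.ones(small_grid.shape))
            for n in dt.METRIC_NAMES[:-1]
        }
        with pytest.raises(ValueError, match="missing"):
            dt.build_feature_matrix(metrics, mask_vol)


class TestNormalizeMax:
    def test_column_divided_by_its_max(self):
        fm = dt.normalize_max(fm_from_values([[0.2, 3.0], [0.4, 1.5]]))
        assert fm.values[:, 0].tolist() == [0.5, 1.0]
        assert fm.values[:, 1].tolist() == [1.0, 0.5]

    def test_constant_column_becomes_ones(self):
        fm = dt.normalize_max(fm_from_values([[2.0], [2.0], [2.0]]))
        assert fm.values.tolist() == [[1.0], [1.0], [1.0]]

    def test_output_maxima_are_one(self, rng):
        fm = dt.normalize_max(fm_from_values(rng.random((40, 7)) + 0.1))
        assert np.allclose(fm.values.max(axis=0), 1.0)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            dt.normalize_max(fm_from_values([[0.0], [0.0]]))


class TestReplaceOutliersIQR:
    def test_hand_computed_example(self):
        # column (1,2,3,4,100): Q1=2, Q3=4, fences (-1, 7); 100 -> median 3
        fm = dt.replace_outliers_iqr(fm_from_values([[1], [2], [3], [4], [100]]))
        assert fm.values.ravel().tolist() == [1, 2, 3, 4, 3]

    def test_no_outliers_unchanged(self):
        values = [[1.0], [2.0], [3.0], [4.0], [5.0]]
        fm = dt.replace_outliers_iqr(fm_from_values(values))
        assert fm.values.tolist() == values

    def test_idempotent(self):
        fm = dt.replace_outliers_iqr(fm_from_values([[1], [2], [3], [4], [100]]))
        again = dt.replace_outliers_iqr(fm)
        assert np.array_equal(fm.values, again.values)

    def test_needs_four_rows(self):
        with pytest.raises(ValueError, match="at least 4"):
            dt.replace_outliers_iqr(fm_from_values([[1], [2], [3]]))


class TestFuzzyCMeans:
    def test_separated_clouds_recovered(self, rng):
        """Two 7-D clouds 10 sd apart: memberships harden, centroids land on means."""
        mu_a = np.full(7, 0.3)
        mu_b = np.full(7, 0.8)  # separation 0.5 = 10 * sd
        sd = 0.05
        x = np.vstack(
            [rng.normal(mu_a, sd, size=(60, 7)), rng.normal(mu_b, sd, size=(60, 7))]
        )
        fp = dt.fuzzy_cmeans(fm_from_values(x), dt.FCMConfig(n_clusters=2, seed=3))
        assert fp.memberships.max(axis=1).min() > 0.95
        order = np.argsort(fp.centroids[:, 0])
        assert np.abs(fp.centroids[order[0]] - mu_a).max() < 0.05
        assert np.abs(fp.centroids[order[1]] - mu_b).max() < 0.05

    def test_equidistant_point_has_symmetric_membership(self):
        u = _membership_from_distances(np.array([[4.0, 4.0]]), m=2.0)
        assert u.tolist() == [[0.5, 0.5]]

    def test_coincident_point_gets_full_membership(self):
        u = _membership_from_distances(np.array([[0.0, 9.0]]), m=2.0)
        assert u.tolist() == [[1.0, 0.0]]

    def test_objective_non_increasing_on_random_data(self, rng):
        for i in range(20):
            x = rng.random((30, 4))
            fp = dt.fuzzy_cmeans(
                fm_from_values(x), dt.FCMConfig(n_clusters=3, seed=i, n_restarts=1)
            )
            diffs = np.diff(fp.objective_history)
            assert np.all(diffs <= 1e-9 * max(1.0, fp.objective_history[0]))

    def test_memberships_row_stochastic(self, rng):
        x = rng.random((50, 7))
        fp = dt.fuzzy_cmeans(fm_from_values(x), dt.FCMConfig(seed=0))
        assert np.allclose(fp.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert fp.memberships.min() >= 0 and fp.memberships.max() <= 1

    def test_centroids_are_fixed_points(self, rng):
        """At convergence, re-applying the centroid update changes nothing much."""
        x = rng.random((80, 3))
        cfg = dt.FCMConfig(n_clusters=2, seed=1, tol=1e-12, max_iter=500)
        fp = dt.fuzzy_cmeans(fm_from_values(x), cfg)
        um = fp.memberships**cfg.fuzziness
        again = (um.T @ x) / um.sum(axis=0)[:, None]
        assert np.allclose(again, fp.centroids, atol=1e-5)

    def test_fewer_points_than_clusters_rejected(self):
        with pytest.raises(ValueError, match="fewer voxels"):
            dt.fuzzy_cmeans(fm_from_values([[1.0, 2.0]]), dt.FCMConfig(n_clusters=3))


class TestAssignMaxMembership:
    def test_argmax_and_tie_rule(self):
        fp = dt.FuzzyPartition(
            memberships=np.array([[0.7, 0.2, 0.1], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]]),
            centroids=np.zeros((3, 2)),
            objective=0.0,
        )
        assert dt.assign_max_membership(fp).tolist() == [1, 1, 3]

    def test_one_hot_recovered_exactly(self, rng):
        labels = rng.integers(0, 3, size=30)
        onehot = np.eye(3)[labels]
        fp = dt.FuzzyPartition(
            memberships=onehot, centroids=np.zeros((3, 2)), objective=0.0
        )
        assert np.array_equal(dt.assign_max_membership(fp), labels + 1)


class TestReduceToTwo:
    def make_three_cluster_fm(self, spread=0.1):
        """9 voxels along x: labels 1,2 close in feature space, 3 far."""
        grid = dt.default_grid(shape=(9, 3, 3), voxel_mm=1.0)
        idx = np.column_stack([np.arange(9), np.ones(9, int), np.ones(9, int)])
        feats = np.zeros((9, 2))
        labels = np.array([3, 3, 3, 1, 1, 1, 2, 2, 2])
        feats[labels == 1] = [0.0, 0.0]
        feats[labels == 2] = [spread, 0.0]
        feats[labels == 3] = [1.0, 1.0]
        return fm_from_values(feats, grid=grid, indices=idx), labels, grid

    def test_closest_pair_merged(self):
        fm, labels, grid = self.make_three_cluster_fm()
        mask = make_label_volume(grid, np.ones(grid.shape, dtype=int), {1: "DN"})
        out = dt.reduce_to_two(labels, fm, mask)
        merged = out.labels[fm.voxel_indices[:, 0], 1, 1]
        # clusters 1 and 2 (distance 0.1) merge; cluster 3 survives alone
        assert len(set(merged[labels == 1]) | set(merged[labels == 2])) == 1
        assert set(merged[labels == 3]) != set(merged[labels == 1])

    def test_two_clusters_only_renamed(self):
        grid = dt.default_grid(shape=(8, 3, 3), voxel_mm=1.0)
        idx = np.column_stack([np.arange(8), np.ones(8, int), np.ones(8, int)])
        feats = np.tile([[0.0], [1.0]], (4, 1))
        labels = np.array([1, 2, 1, 2, 1, 2, 1, 2])
        fm = fm_from_values(feats, grid=grid, indices=idx)
        mask = make_label_volume(grid, np.ones(grid.shape, dtype=int), {1: "DN"})
        out = dt.reduce_to_two(labels, fm, mask)
        assert set(out.label_names.values()) == {"lateral", "medial"}
        got = out.labels[idx[:, 0], 1, 1]
        # original partition preserved, only relabelled
        assert len(set(got[labels == 1])) == 1 and len(set(got[labels == 2])) == 1

    def test_medial_label_is_nearer_midline(self, phantom, spec, rng):
        mask_l, _, _, truth_micro = phantom
        metrics = dt.simulate_metrics(truth_micro, spec, rng)
        atlas, _ = dt.microstructure_atlas(metrics, mask_l, dt.FCMConfig(seed=0))
        idx = dt.mask_indices(mask_l, 1)
        x = mask_l.grid.world_coordinates(idx)[:, 0]
        got = atlas.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert np.abs(x[got == 2]).mean() < np.abs(x[got == 1]).mean()

    def test_single_cluster_rejected(self):
        fm = fm_from_values(np.zeros((5, 2)))
        grid = fm.grid
        mask = make_label_volume(grid, np.ones(grid.shape, dtype=int), {1: "DN"})
        with pytest.raises(ValueError, match="at least 2"):
            dt.reduce_to_two(np.ones(5, dtype=int), fm, mask)


class TestFullChain:
    def test_planted_clusters_recovered(self, phantom, spec):
        """Normalise -> IQR -> FCM(c=3) -> harden -> reduce recovers the truth."""
        mask_l, _, _, truth_micro = phantom
        rng = np.random.default_rng(42)
        metrics = dt.simulate_metrics(truth_micro, spec, rng)
        atlas, fp = dt.microstructure_atlas(metrics, mask_l, dt.FCMConfig(seed=0))
        idx = dt.mask_indices(mask_l, 1)
        got = atlas.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        want = truth_micro.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert (got == want).mean() >= 0.95
        assert np.all(np.diff(fp.objective_history) <= 1e-9 * fp.objective_history[0])

    def test_order_equivariance(self, rng):
        """Permuting voxel rows permutes the hardened labels identically."""
        x = np.vstack(
            [rng.normal(0.3, 0.02, size=(40, 7)), rng.normal(0.7, 0.02, size=(40, 7))]
        )
        fm = fm_from_values(x)
        cfg = dt.FCMConfig(n_clusters=2, seed=5)
        labels = dt.assign_max_membership(dt.fuzzy_cmeans(fm, cfg))
        perm = rng.permutation(len(x))
        fm_p = fm_from_values(x[perm])
        labels_p = dt.assign_max_membership(dt.fuzzy_cmeans(fm_p, cfg))
        # cluster ids may swap between runs; compare the induced partitions
        same = labels[perm] == labels[perm][0]
        same_p = labels_p == labels_p[0]
        assert np.array_equal(same, same_p)
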