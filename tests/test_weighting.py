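import numpy as np
import pytest

import hybci as h
from hybci.errors import (ClassCoverageError, DegenerateInputError,
                          MissingLabelError, ShapeError)
from oracles import min_sse_bipartition, min_sse_bipartition_1d


def _table(X, y, name="t"):
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    return h.FeatureTable(X=X, y=np.asarray(y, int),
                          names=[f"f{i}" for i in range(X.shape[1])], name=name)


class TestKMeans2:
    def test_two_points_are_their_own_centers(self):
        res = h.kmeans2(np.array([0.0, 10.0]), seed=0)
        assert sorted(res.centers.ravel()) == [0.0, 10.0]
        assert res.converged

    def test_two_pairs_1d(self):
        res = h.kmeans2(np.array([0.0, 1.0, 10.0, 11.0]), seed=1)
        assert sorted(res.centers.ravel()) == [0.5, 10.5]

    def test_two_pairs_2d(self):
        # best of several restarts reaches the exhaustive-optimum centers
        pts = np.array([(0, 0), (0, 1), (10, 0), (10, 1)], dtype=float)
        res = min((h.kmeans2(pts, seed=s) for s in range(10)),
                  key=lambda r: r.sse)
        got = sorted(map(tuple, res.centers))
        assert got == [(0.0, 0.5), (10.0, 0.5)]

    def test_assignments_to_nearer_center(self, rng):
        pts = rng.normal(size=(30, 3))
        res = h.kmeans2(pts, seed=4)
        d = ((pts[:, None, :] - res.centers[None]) ** 2).sum(axis=2)
        np.testing.assert_array_equal(res.assignments, np.argmin(d, axis=1))
        assert 0 < res.assignments.sum() < len(pts)  # no empty cluster

    def test_identical_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            h.kmeans2(np.full((5, 2), 3.0), seed=0)

    def test_matches_exhaustive_2d_partition(self, rng):
        pts = rng.normal(size=(8, 2))
        best_sse, _ = min_sse_bipartition(pts)
        sse = min(h.kmeans2(pts, seed=s).sse for s in range(10))
        assert sse == pytest.approx(best_sse, rel=1e-9)


class TestClassCenter:
    def test_mean_of_two_centers(self):
        assert h.class_center(np.array([0.0, 1.0, 10.0, 11.0]), seed=0) == \
            pytest.approx([5.5])

    def test_degenerate_class_falls_back_to_mean(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            z = h.class_center(np.full(4, 5.0), seed=0)
        assert z == pytest.approx([5.0])

    def test_symmetric_data_centered_on_mean(self):
        pts = np.array([-3.0, -1.0, 1.0, 3.0]) + 7.0
        assert h.class_center(pts, seed=2) == pytest.approx([7.0])


class TestKMCC:
    def test_symmetric_classes_give_identity_weights(self):
        X = np.concatenate([[0.0, 1.0, 10.0, 11.0], [2.0, 3.0, 12.0, 13.0]])
        y = [1] * 4 + [2] * 4
        cw = h.kmcc_weights(_table(X, y), seed=0)
        np.testing.assert_allclose(cw.w, 1.0)
        out = h.apply_weights(_table(X, y), cw, mode="faithful")
        np.testing.assert_allclose(out.X, _table(X, y).X)

    def test_single_feature_scale_equivariance_per_feature_mode(self, rng):
        # with 1-D (per-feature) clustering, scaling feature j rescales both
        # mu[i][j] and z[i][j], leaving w[i][j] exactly unchanged
        X = rng.uniform(1, 5, size=(40, 3))
        y = np.tile([1, 2], 20)
        w_base = h.kmcc_weights(_table(X, y), seed=3, per_feature=True).w
        X2 = X.copy()
        X2[:, 1] *= 7.5
        w_scaled = h.kmcc_weights(_table(X2, y), seed=3, per_feature=True).w
        np.testing.assert_allclose(w_scaled, w_base, rtol=1e-9)

    def test_isotropic_scale_equivariance_full_matrix(self, rng):
        # full-matrix clustering preserves its partition under isotropic
        # scaling, so scaling every feature by the same a leaves w unchanged
        X = rng.uniform(1, 5, size=(40, 3))
        y = np.tile([1, 2], 20)
        w_base = h.kmcc_weights(_table(X, y), seed=3).w
        w_scaled = h.kmcc_weights(_table(X * 6.0, y), seed=3).w
        np.testing.assert_allclose(w_scaled, w_base, rtol=1e-9)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ClassCoverageError):
            h.kmcc_weights(_table(rng.normal(size=(6, 2)), [1] * 6), seed=0)


class TestKMCCD:
    def test_hand_computed_1d_example(self):
        # class {0,1,10,11}: z = 5.5, distances {5.5,4.5,4.5,5.5}, mu = 5
        X = np.concatenate([[0.0, 1.0, 10.0, 11.0], [0.0, 1.0, 10.0, 11.0]])
        y = [1] * 4 + [2] * 4
        cw = h.kmccd_weights(_table(X, y), seed=0)
        np.testing.assert_allclose(cw.w, 5.0 / 5.5)

    def test_constant_class_features_give_zero_weights(self):
        X = np.array([[4.0, 1.0]] * 3 + [[4.0, 2.0]] * 3)
        y = [1] * 3 + [2] * 3
        with pytest.warns(RuntimeWarning):
            cw = h.kmccd_weights(_table(X, y), seed=0)
        np.testing.assert_allclose(cw.w, 0.0)
        out = h.apply_weights(_table(X, y), cw, mode="faithful")
        np.testing.assert_allclose(out.X, 0.0)

    def test_matches_brute_force_recomputation(self, rng):
        X = rng.uniform(0.5, 4.0, size=(30, 4))
        y = np.tile([1, 2], 15)
        cw = h.kmccd_weights(_table(X, y), seed=5)
        shared = np.random.default_rng(5)  # weights share one seeded stream
        for i, cls in enumerate((1, 2)):
            sub = X[np.asarray(y) == cls]
            z = h.kmeans2(sub, seed=shared).centers.mean(0)
            mu = np.abs(sub - z).mean(0)
            np.testing.assert_allclose(cw.z[i], z)
            np.testing.assert_allclose(cw.w[i], mu / z)

    def test_not_translation_invariant(self, rng):
        X = rng.uniform(1, 3, size=(20, 2))
        y = np.tile([1, 2], 10)
        w0 = h.kmccd_weights(_table(X, y), seed=1).w
        w1 = h.kmccd_weights(_table(X + 10.0, y), seed=1).w
        assert not np.allclose(w0, w1)

    def test_scale_equivariance(self, rng):
        X = rng.uniform(1, 5, size=(40, 3))
        y = np.tile([1, 2], 20)
        w_base = h.kmccd_weights(_table(X, y), seed=3).w
        X2 = X * 4.0
        w_scaled = h.kmccd_weights(_table(X2, y), seed=3).w
        np.testing.assert_allclose(w_scaled, w_base, rtol=1e-9)


class TestApplyWeights:
    def _cw(self, w):
        w = np.asarray(w, float)
        return h.ClassWeights(w=w, z=np.ones_like(w), mu=w.copy(),
                              method="kmcc")

    def test_unit_weights_identity(self, rng):
        t = _table(rng.normal(size=(4, 2)), [1, 2, 1, 2])
        out = h.apply_weights(t, self._cw(np.ones((2, 2))), mode="faithful")
        np.testing.assert_array_equal(out.X, t.X)

    def test_faithful_uses_own_label(self):
        t = _table([[5.0], [5.0]], [1, 2])
        out = h.apply_weights(t, self._cw([[2.0], [3.0]]), mode="faithful")
        np.testing.assert_allclose(out.X.ravel(), [10.0, 15.0])

    def test_global_uses_mean_weight(self):
        t = _table([[5.0], [5.0]], [1, 2])
        out = h.apply_weights(t, self._cw([[2.0], [3.0]]), mode="global")
        np.testing.assert_allclose(out.X.ravel(), [12.5, 12.5])

    def test_unknown_label_rejected_in_faithful_mode(self):
        t = _table([[5.0], [5.0]], [1, 3])
        with pytest.raises(MissingLabelError):
            h.apply_weights(t, self._cw([[2.0], [3.0]]), mode="faithful")

    def test_feature_count_mismatch(self):
        t = _table([[5.0, 1.0], [5.0, 1.0]], [1, 2])
        with pytest.raises(ShapeError):
            h.apply_weights(t, self._cw([[2.0], [3.0]]), mode="faithful")


def test_kmeans_matches_sklearn_on_well_separated_data(rng):
    """Independent library cross-check of the Lloyd core."""
    from sklearn.cluster import KMeans

    pts = np.vstack([rng.normal(0, 0.5, (20, 2)), rng.normal(8, 0.5, (20, 2))])
    ours = min((h.kmeans2(pts, seed=s) for s in range(5)), key=lambda r: r.sse)
    ref = KMeans(n_clusters=2, n_init=5, random_state=0).fit(pts)
    np.testing.assert_allclose(
        np.sort(ours.centers, axis=0), np.sort(ref.cluster_centers_, axis=0),
        rtol=1e-6)
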