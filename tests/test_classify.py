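import numpy as np
import pytest

import hybci as h
from hybci.errors import ShapeError, StratificationError, TrainingError


def _table(X, y, name="t"):
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    return h.FeatureTable(X=X, y=np.asarray(y, int),
                          names=[f"f{i}" for i in range(X.shape[1])], name=name)


class TestStratifiedKFold:
    def test_reference_fold_sizes(self):
        y = np.tile([1, 2], 870)  # 1740 balanced observations
        folds = h.stratified_kfold(y, k=10, seed=0)
        for f in range(10):
            in_fold = folds == f
            assert in_fold.sum() == 174
            assert (in_fold & (y == 1)).sum() == 87

    def test_fold_sizes_with_remainder(self):
        y = np.tile([1, 2], 52)  # 104 observations, 10 folds
        folds = h.stratified_kfold(y, k=10, seed=1)
        sizes = np.bincount(folds, minlength=10)
        assert set(sizes) <= {10, 11}
        assert sizes.sum() == 104

    def test_deterministic_per_seed(self):
        y = np.tile([1, 2], 50)
        np.testing.assert_array_equal(h.stratified_kfold(y, seed=7),
                                      h.stratified_kfold(y, seed=7))
        assert not np.array_equal(h.stratified_kfold(y, seed=7),
                                  h.stratified_kfold(y, seed=8))

    def test_small_class_rejected(self):
        with pytest.raises(StratificationError):
            h.stratified_kfold([1] * 50 + [2] * 5, k=10)


class TestFitPredict:
    def test_knn_exact_match_returns_its_label(self, rng):
        train = _table(rng.normal(size=(10, 3)), np.tile([1, 2], 5))
        test = _table(train.X[[3]], [0])
        assert h.fit_predict("knn", train, test)[0] == train.y[3]

    def test_knn_distance_tie_prefers_lower_row_index(self):
        train = _table([[-1.0], [1.0]], [2, 1])
        test = _table([[0.0]], [0])  # equidistant from both
        assert h.fit_predict("knn", train, test)[0] == 2

    def test_lda_separates_well_separated_gaussians(self):
        rng = np.random.default_rng(42)
        X = np.concatenate([rng.normal(-5, 1, 100), rng.normal(5, 1, 100)])
        y = np.array([1] * 100 + [2] * 100)
        train = _table(X, y)
        pred = h.fit_predict("lda", train, train)
        assert np.mean(pred == y) >= 0.99

    def test_svm_separable_toy(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1],
                      [4, 0], [4, 1], [5, 0], [5, 1]], dtype=float)
        y = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        t = _table(X, y)
        np.testing.assert_array_equal(h.fit_predict("svm", t, t), y)

    def test_single_class_training_rejected(self, rng):
        train = _table(rng.normal(size=(5, 2)), [1] * 5)
        with pytest.raises(TrainingError):
            h.fit_predict("lda", train, train)

    def test_unknown_classifier_rejected(self, rng):
        t = _table(rng.normal(size=(4, 2)), [1, 2, 1, 2])
        with pytest.raises(ValueError):
            h.fit_predict("forest", t, t)


class TestConfusion:
    @pytest.mark.parametrize("truth,pred,expected", [
        ([1, 1, 2, 2], [1, 1, 2, 2], (2, 2, 0, 0)),
        ([1, 2], [2, 1], (0, 0, 1, 1)),
        ([1, 1, 1, 2], [1, 2, 1, 1], (2, 0, 1, 1)),
    ])
    def test_hand_counts(self, truth, pred, expected):
        c = h.confusion(truth, pred)
        assert (c.tp, c.tn, c.fp, c.fn) == expected

    def test_total_conserved(self, rng):
        truth = rng.integers(1, 3, 100)
        pred = rng.integers(1, 3, 100)
        assert h.confusion(truth, pred).total == 100

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            h.confusion([1, 2], [1, 2, 1])


class TestMetrics:
    def test_perfect_classifier(self):
        m = h.metrics(h.ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (m.acc, m.sens, m.fpr, m.prc, m.kappa) == (100.0, 1.0, 0.0, 1.0, 1.0)
        assert m.error == 0.0 and m.ci == 0.0

    def test_chance_agreement(self):
        m = h.metrics(h.ConfusionCounts(25, 25, 25, 25))
        assert m.acc == 50.0
        assert m.kappa == 0.0

    def test_confidence_interval_formula(self):
        # error 0.1 on n = 1740: 1.96 * sqrt(0.1 * 0.9 / 1740)
        m = h.metrics(h.ConfusionCounts(tp=100, tn=1466, fp=87, fn=87), n=1740)
        assert m.error == pytest.approx(0.1)
        assert m.ci == pytest.approx(0.0141, abs=5e-5)

    def test_undefined_metrics_are_nan_not_zero(self):
        m = h.metrics(h.ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert np.isnan(m.prc)  # TP + FP = 0
        m = h.metrics(h.ConfusionCounts(tp=5, tn=0, fp=0, fn=0))
        assert np.isnan(m.fpr)  # FP + TN = 0

    def test_error_acc_identity(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 50, 4)
            if tp + tn + fp + fn == 0:
                continue
            m = h.metrics(h.ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert m.acc / 100 + m.error == pytest.approx(1.0)

    def test_kappa_one_iff_no_errors(self, rng):
        assert h.metrics(h.ConfusionCounts(30, 20, 0, 0)).kappa == pytest.approx(1.0)
        assert h.metrics(h.ConfusionCounts(30, 20, 1, 0)).kappa < 1.0

    def test_kappa_near_zero_for_permuted_predictions(self):
        rng = np.random.default_rng(8)
        truth = rng.integers(1, 3, 1000)
        kappas = []
        for _ in range(20):
            pred = rng.permutation(truth)
            kappas.append(h.metrics(h.confusion(truth, pred)).kappa)
        assert abs(np.mean(kappas)) < 0.05

    def test_printed_formula_variants(self):
        c = h.ConfusionCounts(tp=40, tn=30, fp=20, fn=10)
        assert h.metrics(c, printed_acc=True).acc == pytest.approx(60.0)
        assert h.metrics(c, printed_fpr=True).fpr == pytest.approx(20 / 70)
        m = h.metrics(c, printed_p2=True)
        p1 = 0.5
        random_acc = p1 * p1 + (1 - p1) * (1 - p1)
        assert m.kappa == pytest.approx((0.7 - random_acc) / (1 - random_acc))


class TestRunExperiment:
    def test_grid_has_54_cells(self, small_tables):
        rep = h.run_experiment(small_tables, folds=3, seed=0)
        assert len(rep.cells) == 6 * 3 * 3
        df = rep.to_dataframe()
        assert len(df) == 54

    def test_fold_conservation(self, small_tables):
        rep = h.run_experiment(small_tables, classifiers=("knn",),
                               weightings=("none",), folds=3, seed=1)
        cell = rep.cell("hbo", "knn", "none")
        assert cell.counts.total == small_tables["hbo"].n_obs
        assert len(cell.fold_acc) == 3

    def test_bit_identical_reproducibility(self, small_tables):
        kw = dict(classifiers=("knn", "lda"), weightings=("none", "kmccd"),
                  folds=3, seed=5)
        a = h.run_experiment(small_tables, **kw)
        b = h.run_experiment(small_tables, **kw)
        for key in a.cells:
            assert a.cells[key].as_dict() == b.cells[key].as_dict()

    def test_label_mismatch_between_tables_rejected(self, rng):
        a = _table(rng.normal(size=(8, 2)), np.tile([1, 2], 4))
        b = _table(rng.normal(size=(8, 2)), np.tile([2, 1], 4))
        with pytest.raises(ShapeError):
            h.run_experiment({"a": a, "b": b}, folds=2, seed=0)

    def test_zero_effect_data_classifies_at_chance(self):
        """No class signal and no weighting leaves accuracy near 50%."""
        accs = []
        for seed in range(10):
            cfg = h.SimConfig(n_subjects=2, n_sessions=1, trials_per_session=10,
                              n_nirs_channels=4, n_eeg_channels=4,
                              fs_eeg_raw=200.0, hemo_effect_size=1.0,
                              erd_effect_size=1.0, seed=seed)
            tabs = h.run_synthetic_pipeline(cfg)
            rep = h.run_experiment({"hbo": tabs["hbo"], "eeg": tabs["eeg"]},
                                   classifiers=("knn", "lda"),
                                   weightings=("none",), folds=5, seed=seed)
            accs.extend([rep.cell("hbo", "knn", "none").acc,
                         rep.cell("hbo", "lda", "none").acc,
                         rep.cell("eeg", "knn", "none").acc,
                         rep.cell("eeg", "lda", "none").acc])
        assert np.mean(accs) == pytest.approx(50.0, abs=5.0)
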