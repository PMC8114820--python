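"""Cross-validated classification grid and confusion-matrix metrics.

Runs the feature-set x classifier x weighting grid under stratified
10-fold cross-validation and computes accuracy, sensitivity, false
positive rate, precision, Cohen's kappa, the classification error, and a
binomial normal-approximation confidence half-width:

    ACC% = 100 (TP+TN)/total        Sens = TP/(TP+FN)
    FPR  = FP/(FP+TN)               PRC  = TP/(TP+FP)
    kappa = (acc - p1 p2 - (1-p1)(1-p2)) / (1 - p1 p2 - (1-p1)(1-p2)),
        p1 = (TP+FN)/total, p2 = (TP+FP)/total
    error = (FP+FN)/total,  CI = z * sqrt(error (1-error) / n)

with z = 1.96 at 95% confidence and n the number of observations used to
develop the model (the full table size, not the fold size).  Headline
metrics are computed from the confusion matrix pooled over folds;
per-fold accuracies are retained in the report.

Classifiers: plain pooled-covariance LDA, soft-margin linear SVM (C = 1),
and 1-nearest-neighbor with Euclidean distance (distance ties broken by
the lower training-row index, which is why 1-NN is implemented directly
rather than through a library whose tie-break is unspecified).

Weighting modes: ``faithful`` computes KMCC/KMCCD weights on the full
table and applies them label-wise *before* folding, replicating the
original protocol including its label leakage; ``global`` fits weights
within each training fold and applies the label-free averaged vector to
that fold's training and test rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import nan, sqrt

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import norm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ShapeError, StratificationError, TrainingError
from .features import FeatureTable
from .weighting import apply_weights, kmcc_weights, kmccd_weights

__all__ = [
    "ConfusionCounts",
    "MetricCell",
    "EvalReport",
    "stratified_kfold",
    "fit_predict",
    "confusion",
    "metrics",
    "run_experiment",
]

CLASSIFIERS = ("knn", "lda", "svm")
WEIGHTINGS = ("none", "kmcc", "kmccd")

#: Iteration cap for the libsvm solver.  Faithfully weighted tables mix
#: feature scales over ~10 orders of magnitude, on which libsvm's
#: active-set solver may never reach its KKT tolerance; the cap bounds the
#: fit and a ConvergenceWarning is emitted when it is hit.
SVM_MAX_ITER = 100_000


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricCell:
    """Metric suite of one (feature set, classifier, weighting) cell."""

    acc: float          # percent
    sens: float
    fpr: float
    prc: float
    kappa: float
    error: float
    ci: float           # half-width of the error confidence interval
    n: int
    counts: ConfusionCounts | None = None
    fold_acc: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "acc": self.acc, "sens": self.sens, "fpr": self.fpr,
            "prc": self.prc, "kappa": self.kappa, "error": self.error,
            "ci": self.ci, "n": self.n, "fold_acc": list(self.fold_acc),
        }


def stratified_kfold(labels, k: int = 10, seed=0) -> np.ndarray:
    """Fold index per observation for stratified k-fold CV.

    Folds are sized floor(n/k) or ceil(n/k) with class proportions
    preserved per fold within one observation; deterministic per seed.
    """
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} members, fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    assignment = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = f
    return assignment


def _knn1_predict(train_X, train_y, test_X):
    d = cdist(test_X, train_X)          # Euclidean
    nearest = np.argmin(d, axis=1)      # ties -> lowest training-row index
    return train_y[nearest]


def fit_predict(classifier: str, train: FeatureTable,
                test: FeatureTable) -> np.ndarray:
    """Train one classifier on ``train`` and predict labels for ``test``."""
    if len(np.unique(train.y)) < 2:
        raise TrainingError("training fold contains a single class")
    if classifier == "knn":
        return _knn1_predict(train.X, train.y, test.X)
    if classifier == "lda":
        model = LinearDiscriminantAnalysis(solver="svd")
    elif classifier == "svm":
        model = SVC(kernel="linear", C=1.0, cache_size=200,
                    max_iter=SVM_MAX_ITER)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    model.fit(train.X, train.y)
    return model.predict(test.X)


def confusion(true_labels, predicted, positive: int = 1) -> ConfusionCounts:
    """Standard binary confusion counts with class ``positive`` as positive."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise ShapeError("true and predicted label lengths differ")
    pos_t = t == positive
    pos_p = p == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _z_constant(confidence: float) -> float:
    # table value at the conventional level; exact quantile otherwise
    return 1.96 if confidence == 0.95 else float(norm.ppf(0.5 + confidence / 2))


def metrics(c: ConfusionCounts, n: int | None = None, confidence: float = 0.95,
            printed_acc: bool = False, printed_fpr: bool = False,
            printed_p2: bool = False) -> MetricCell:
    """Metric suite from pooled confusion counts.

    ``n`` is the number of observations used to develop the model (defaults
    to ``c.total``).  A metric with a zero denominator is reported as NaN
    rather than 0.  The ``printed_*`` flags switch individual formulas to
    literal variants found in some write-ups (accuracy numerator TP+FP,
    FPR denominator TP+TN, p2 defined identically to p1); the defaults are
    the standard definitions.
    """
    total = c.total
    if total <= 0:
        raise ValueError("confusion counts are empty")
    if n is None:
        n = total

    acc_num = (c.tp + c.fp) if printed_acc else (c.tp + c.tn)
    acc = 100.0 * acc_num / total
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else nan
    fpr_den = (c.tp + c.tn) if printed_fpr else (c.fp + c.tn)
    fpr = c.fp / fpr_den if fpr_den else nan
    prc = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else nan

    p1 = (c.tp + c.fn) / total
    p2 = p1 if printed_p2 else (c.tp + c.fp) / total
    random_acc = p1 * p2 + (1 - p1) * (1 - p2)
    acc_frac = acc_num / total
    kappa = ((acc_frac - random_acc) / (1 - random_acc)
             if random_acc != 1.0 else nan)

    error = (c.fp + c.fn) / total
    ci = _z_constant(confidence) * sqrt(error * (1 - error) / n)
    return MetricCell(acc=acc, sens=sens, fpr=fpr, prc=prc, kappa=kappa,
                      error=error, ci=ci, n=n, counts=c)


@dataclass
class EvalReport:
    """Grid of metric cells keyed by (feature_set, classifier, weighting)."""

    cells: dict
    n: int
    folds: int
    seed: int
    mode: str

    def cell(self, feature_set: str, classifier: str,
             weighting: str) -> MetricCell:
        return self.cells[(feature_set, classifier, weighting)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (fs_name, clf, wgt), cell in self.cells.items():
            rows.append({
                "feature_set": fs_name, "classifier": clf, "weighting": wgt,
                "ACC (%)": cell.acc, "SENS": cell.sens, "FPR": cell.fpr,
                "PRC": cell.prc, "Kappa": cell.kappa,
                "error": cell.error, "CI": cell.ci,
                "classification_error": f"{cell.error:.3f} ± {cell.ci:.3f}",
            })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        nested: dict = {}
        for (fs_name, clf, wgt), cell in self.cells.items():
            nested.setdefault(fs_name, {}).setdefault(clf, {})[wgt] = cell.as_dict()
        return json.dumps({
            "config": {"n": self.n, "folds": self.folds, "seed": self.seed,
                       "mode": self.mode},
            "results": nested,
        }, indent=2)

    def summary(self) -> str:
        df = self.to_dataframe()
        cols = ["feature_set", "classifier", "weighting", "ACC (%)", "SENS",
                "FPR", "PRC", "Kappa", "classification_error"]
        return df[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}")


def _weights_fn(weighting: str):
    return {"kmcc": kmcc_weights, "kmccd": kmccd_weights}[weighting]


def run_experiment(tables, classifiers=CLASSIFIERS, weightings=WEIGHTINGS,
                   mode: str = "faithful", folds: int = 10, seed: int = 0,
                   n_for_ci: int | None = None) -> EvalReport:
    """Run the full grid of feature sets x classifiers x weightings.

    ``tables`` maps feature-set names to :class:`FeatureTable` objects that
    must share labels and trial ordering.  In ``faithful`` mode weights are
    computed once on the full table and applied label-wise before folding
    (the replication protocol, leaky by construction); in ``global`` mode
    weights are fitted inside each training fold and the averaged vector is
    applied to both that fold's training and test rows.
    """
    names = list(tables)
    ref_y = tables[names[0]].y
    for nm in names[1:]:
        if not np.array_equal(tables[nm].y, ref_y):
            raise ShapeError(f"table {nm!r} labels differ from {names[0]!r}")
    ss = np.random.SeedSequence(seed)
    fold_seed, weight_seed = (int(s) % (2 ** 31) for s in
                              ss.generate_state(2, dtype=np.uint32))
    fold_of = stratified_kfold(ref_y, k=folds, seed=fold_seed)

    cells = {}
    for fs_name in names:
        table = tables[fs_name]
        for wgt in weightings:
            # fold -> (train_table, test_table); built once per weighting
            prepared = []
            if wgt == "none" or mode == "faithful":
                if wgt == "none":
                    full = table
                else:
                    cw = _weights_fn(wgt)(table, seed=weight_seed)
                    full = apply_weights(table, cw, mode="faithful")
                for f in range(folds):
                    test_idx = fold_of == f
                    prepared.append((full.subset(~test_idx),
                                     full.subset(test_idx)))
            elif mode == "global":
                for f in range(folds):
                    test_idx = fold_of == f
                    tr, te = table.subset(~test_idx), table.subset(test_idx)
                    cw = _weights_fn(wgt)(tr, seed=weight_seed)
                    prepared.append((apply_weights(tr, cw, mode="global"),
                                     apply_weights(te, cw, mode="global")))
            else:
                raise ValueError(f"unknown mode {mode!r}")

            for clf in classifiers:
                pooled = ConfusionCounts(0, 0, 0, 0)
                fold_acc = []
                for tr, te in prepared:
                    pred = fit_predict(clf, tr, te)
                    cm = confusion(te.y, pred)
                    pooled = pooled + cm
                    fold_acc.append((cm.tp + cm.tn) / cm.total)
                cell = metrics(pooled, n=n_for_ci or table.n_obs)
                cell.fold_acc = fold_acc
                cells[(fs_name, clf, wgt)] = cell
    return EvalReport(cells=cells, n=len(ref_y), folds=folds, seed=seed,
                      mode=mode)
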