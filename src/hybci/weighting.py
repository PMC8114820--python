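"""k-means cluster-center attribute weighting (KMCC and KMCCD).

Per-class, per-feature weights are ratios against a k-means-derived class
center z_i:

* KMCC:  w[i][j] = mu[i][j] / z[i][j], where mu[i][j] is the mean of
  feature j within class i;
* KMCCD: w[i][j] = mu_d[i][j] / z[i][j], where mu_d[i][j] is the class
  mean of the point-to-center distances |c[i][j] - z[i][j]|.

z_i is obtained by running 2-means *within* class i and averaging the two
resulting centers componentwise (the pseudo-code's single per-class center
read coherently; see docs/methods.md).  The Lloyd core is hand-rolled so
its seeding, tie-breaking, and empty-cluster policy are fully specified
and testable against a brute-force minimum-SSE bipartition oracle.

Two application modes exist.  ``faithful`` multiplies each observation by
the weight vector of its OWN class label - exactly what the original
pseudo-code prescribes, including on held-out data.  Because this injects
the label into the features before any train/test split, cross-validated
accuracy after faithful weighting is optimistically biased (dramatically
so; pure-noise features classify near-perfectly).  ``global`` applies the
label-free averaged weight vector (w[1]+w[2])/2 to every row and is the
honest variant.  The faithful mode is retained as the replication default;
the leakage is demonstrated in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ClassCoverageError, DegenerateInputError, MissingLabelError, ShapeError
from .features import FeatureTable

__all__ = [
    "KMeansResult",
    "ClassWeights",
    "kmeans2",
    "class_center",
    "kmcc_weights",
    "kmccd_weights",
    "apply_weights",
]

logger = logging.getLogger(__name__)

#: |z| at or below this is treated as a zero center (division guard).
ZERO_CENTER_TOL = 1e-12


@dataclass
class KMeansResult:
    centers: np.ndarray       # (2, d)
    assignments: np.ndarray   # (n,) cluster index in {0, 1}
    n_iter: int
    converged: bool

    @property
    def sse(self) -> float:
        """Within-cluster sum of squared Euclidean distances."""
        diff = self.centers[self.assignments] - self._points
        return float((diff ** 2).sum())


@dataclass
class ClassWeights:
    """Per-class, per-feature weights with the statistics that produced them.

    ``w``, ``z``, ``mu`` are 2 x n_features; row i corresponds to
    ``class_labels[i]``.  ``mu`` holds feature means for KMCC and mean
    point-to-center distances for KMCCD.
    """

    w: np.ndarray
    z: np.ndarray
    mu: np.ndarray
    method: str
    class_labels: tuple[int, int] = (1, 2)

    def __post_init__(self) -> None:
        for name in ("w", "z", "mu"):
            arr = getattr(self, name)
            if arr.shape != self.w.shape or arr.ndim != 2 or arr.shape[0] != 2:
                raise ShapeError("w, z, mu must all be 2 x n_features")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")

    @property
    def n_features(self) -> int:
        return self.w.shape[1]

    @property
    def mean_weights(self) -> np.ndarray:
        """Label-free averaged weight vector (global mode)."""
        return self.w.mean(axis=0)


def kmeans2(points, tol: float = 1e-6, max_iter: int = 300,
            seed=None) -> KMeansResult:
    """Lloyd's 2-means on an n x d matrix.

    Initialization samples two distinct points; each point is assigned to
    the nearer center (ties to cluster 1, i.e. index 0), centers are
    recomputed as cluster means, and iteration stops when no center moves
    by more than ``tol``.  An emptied cluster is reseeded with the point
    farthest from the surviving center (logged).  All-identical points
    raise :class:`DegenerateInputError`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if n < 2:
        raise DegenerateInputError("kmeans2 requires at least 2 points")
    rng = np.random.default_rng(seed)

    order = rng.permutation(n)
    first = order[0]
    second = next((i for i in order[1:] if not np.array_equal(pts[i], pts[first])),
                  None)
    if second is None:
        raise DegenerateInputError("all points are identical")
    centers = pts[[first, second]].copy()

    assignments = np.zeros(n, dtype=int)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assignments = np.argmin(d, axis=1)  # argmin ties -> index 0
        new_centers = centers.copy()
        for j in range(2):
            members = pts[assignments == j]
            if len(members) == 0:
                other = 1 - j
                far = np.argmax(((pts - centers[other]) ** 2).sum(axis=1))
                new_centers[j] = pts[far]
                assignments[far] = j
                logger.info("kmeans2: cluster %d emptied; reseeded with "
                            "farthest point %d", j, far)
            else:
                new_centers[j] = members.mean(axis=0)
        movement = np.linalg.norm(new_centers - centers, axis=1).max()
        centers = new_centers
        if movement < tol:
            converged = True
            break
    # final assignment consistent with returned centers
    d = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assignments = np.argmin(d, axis=1)
    res = KMeansResult(centers=centers, assignments=assignments,
                       n_iter=it, converged=converged)
    res._points = pts  # for the sse property
    return res


def class_center(class_matrix, seed=None) -> np.ndarray:
    """Single per-class center: componentwise mean of the two 2-means centers.

    A degenerate class (all rows identical, or a single row) falls back to
    the plain class mean with a warning.
    """
    pts = np.asarray(class_matrix, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    try:
        res = kmeans2(pts, seed=seed)
    except DegenerateInputError:
        warnings.warn("degenerate class for k-means; using the class mean",
                      RuntimeWarning, stacklevel=2)
        return pts.mean(axis=0)
    return res.centers.mean(axis=0)


def _split_classes(table: FeatureTable):
    classes = np.unique(table.y)
    if len(classes) != 2:
        raise ClassCoverageError(
            f"weighting requires exactly 2 classes, found {classes.tolist()}"
        )
    subs = []
    for cls in classes:
        sub = table.X[table.y == cls]
        if len(sub) < 2:
            raise ClassCoverageError(
                f"class {cls} has fewer than 2 observations"
            )
        subs.append(sub)
    return (int(classes[0]), int(classes[1])), subs


def _class_centers(subs, seed, per_feature: bool) -> np.ndarray:
    rng = np.random.default_rng(seed)
    z = np.empty((2, subs[0].shape[1]))
    for i, sub in enumerate(subs):
        if per_feature:
            for j in range(sub.shape[1]):
                z[i, j] = class_center(sub[:, j:j + 1], seed=rng)[0]
        else:
            z[i] = class_center(sub, seed=rng)
    return z


def _guard(w: np.ndarray, z: np.ndarray, fill: float) -> np.ndarray:
    """Replace weights whose center is (numerically) zero by ``fill``."""
    bad = np.abs(z) <= ZERO_CENTER_TOL
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} class center(s) are zero; corresponding "
            f"weights set to {fill}", RuntimeWarning, stacklevel=3,
        )
        w = np.where(bad, fill, w)
    return w


def kmcc_weights(table: FeatureTable, seed=None,
                 per_feature: bool = False) -> ClassWeights:
    """Cluster-center weights: class feature means over class centers.

    ``per_feature=True`` runs 2-means per feature column (1-D) instead of
    on the full class matrix.
    """
    labels, subs = _split_classes(table)
    z = _class_centers(subs, seed, per_feature)
    mu = np.stack([sub.mean(axis=0) for sub in subs])
    with np.errstate(divide="ignore", invalid="ignore"):
        w = mu / z
    w = _guard(w, z, fill=1.0)
    return ClassWeights(w=w, z=z, mu=mu, method="kmcc", class_labels=labels)


def kmccd_weights(table: FeatureTable, seed=None,
                  per_feature: bool = False) -> ClassWeights:
    """Cluster-center-difference weights: mean |x - z| distances over centers."""
    labels, subs = _split_classes(table)
    z = _class_centers(subs, seed, per_feature)
    mu = np.stack([np.abs(sub - z[i]).mean(axis=0)
                   for i, sub in enumerate(subs)])
    with np.errstate(divide="ignore", invalid="ignore"):
        w = mu / z
    w = _guard(w, z, fill=0.0)
    return ClassWeights(w=w, z=z, mu=mu, method="kmccd", class_labels=labels)


def apply_weights(table: FeatureTable, cw: ClassWeights,
                  mode: str = "faithful") -> FeatureTable:
    """Multiply features by class weights.

    ``faithful`` uses each observation's own label to pick its weight row
    (the pseudo-code's data_weighted,i = c_i,j * w_i,j; requires labels on
    every row and leaks them - see the module docstring).  ``global`` uses
    the label-free mean weight vector for every observation.
    """
    if table.n_features != cw.n_features:
        raise ShapeError(
            f"table has {table.n_features} features but weights have "
            f"{cw.n_features}"
        )
    if mode == "global":
        X = table.X * cw.mean_weights[None, :]
    elif mode == "faithful":
        known = np.isin(table.y, cw.class_labels)
        if not np.all(known):
            raise MissingLabelError(
                "faithful weighting requires a known class label on every row"
            )
        row = (table.y == cw.class_labels[1]).astype(int)
        X = table.X * cw.w[row]
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'faithful' or 'global'")
    return table.replace(X=X)
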