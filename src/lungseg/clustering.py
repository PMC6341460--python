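"""Lloyd-style intensity clustering: k-means and k-median.

Pixels are clustered on grayscale intensity alone (a 1-D feature), which
is how the segmentation stage separates air background, lung parenchyma
and dense tissue/tumor on a CT slice. k-means minimizes the within-cluster
sum of squared distances

    J(v) = sum_i  (x_i - v_{c(i)})^2 ,   c(i) = argmin_j |x_i - v_j| ,

by alternating nearest-center assignment and member-mean center updates;
k-median replaces the mean by the member median and reports the sum of
absolute deviations, which is less sensitive to outlying intensities.

Both estimators are deterministic given ``random_state``: centers are
initialized by seeded D^2-weighted sampling of k distinct pixel
intensities, the best of ``n_restarts`` runs (lowest objective) is kept,
ties in assignment break to the lowest center index, and the returned
centers are sorted ascending with labels renumbered to match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from ._validation import check_image

__all__ = [
    "ClusterModel",
    "KMeansSegmenter",
    "KMedianSegmenter",
    "objective_j",
    "kmeans_segment",
    "kmedian_segment",
]


@dataclass
class ClusterModel:
    """Result of any intensity segmenter.

    Attributes
    ----------
    centers : ndarray of shape (k,)
        Cluster center intensities, sorted ascending.
    labels : ndarray of shape (H, W)
        Per-pixel nearest-center index in {0..k-1}.
    objective : float
        Final objective (sum of squared deviations for k-means, sum of
        absolute deviations for k-median, best fitness for swarm variants'
        companion objective).
    n_iter : int
    converged : bool
    objective_trace : list of float
        Objective after each iteration of the winning run/restart.
    """

    centers: np.ndarray
    labels: np.ndarray
    objective: float
    n_iter: int
    converged: bool
    objective_trace: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.centers)


def _assign(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-center labels for 1-D intensities; ties -> lowest index."""
    return np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)


def objective_j(img, centers) -> float:
    """Sum over pixels of the squared distance to the nearest center.

    This is the k-means objective J(v): every pixel contributes to
    exactly one cluster, the one whose center is nearest.
    """
    centers = np.atleast_1d(np.asarray(centers, dtype=np.float64))
    if centers.size == 0:
        raise ValueError("centers must be nonempty")
    x = check_image(img).ravel()
    d = np.abs(x[:, None] - centers[None, :]).min(axis=1)
    return float(np.sum(d**2))


def _init_centers(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded D^2-weighted sampling of k distinct intensities.

    The first center is drawn by pixel mass; each further one by mass
    times squared distance to the nearest chosen center, so restarts
    cover the separated intensity modes instead of resampling one.
    Already-chosen values have zero weight, keeping the centers distinct.
    """
    distinct, counts = np.unique(x, return_counts=True)
    if distinct.size < k:
        raise ValueError(
            f"image has {distinct.size} distinct intensities; need >= k={k}"
        )
    centers = [rng.choice(distinct, p=counts / counts.sum())]
    for _ in range(k - 1):
        d2 = np.min(np.abs(distinct[:, None] - np.array(centers)[None, :]), axis=1) ** 2
        w = counts * d2
        centers.append(rng.choice(distinct, p=w / w.sum()))
    return np.array(centers)


def _lloyd(
    x: np.ndarray,
    centers: np.ndarray,
    *,
    center_fn,
    objective_fn,
    tol: float,
    max_iter: int,
):
    """Generic Lloyd iteration on 1-D data.

    ``center_fn`` recomputes a center from its members (mean or median);
    ``objective_fn`` maps per-pixel absolute deviations to the objective.
    Empty clusters are repaired by moving the center to the pixel farthest
    from its currently assigned center.
    """
    k = centers.size
    trace = []
    converged = False
    labels = _assign(x, centers)
    it = 0
    for it in range(1, max_iter + 1):
        new_centers = centers.copy()
        for j in range(k):
            members = x[labels == j]
            if members.size == 0:
                dev = np.abs(x - centers[labels])
                new_centers[j] = x[np.argmax(dev)]
            else:
                new_centers[j] = center_fn(members)
        shift = np.max(np.abs(new_centers - centers))
        centers = new_centers
        labels = _assign(x, centers)
        trace.append(objective_fn(np.abs(x - centers[labels])))
        if shift < tol:
            converged = True
            break
    return centers, labels, trace, it, converged


class _LloydSegmenter(ClusterMixin, BaseEstimator):
    """Shared fit machinery for the two Lloyd-style intensity clusterers."""

    def __init__(
        self,
        k: int = 3,
        tol: float = 1e-6,
        max_iter: int = 300,
        n_restarts: int = 10,
        random_state: int | None = None,
    ):
        self.k = k
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    # subclass hooks
    _center_fn = staticmethod(np.mean)
    _objective_fn = staticmethod(lambda dev: float(np.sum(dev**2)))

    def fit(self, X, y=None):
        """Cluster the intensities of a 2-D image ``X``."""
        if int(self.k) < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        img = check_image(X)
        x = img.ravel()
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, int(self.n_restarts))):
            centers0 = _init_centers(x, int(self.k), rng)
            result = _lloyd(
                x,
                centers0,
                center_fn=self._center_fn,
                objective_fn=self._objective_fn,
                tol=float(self.tol),
                max_iter=int(self.max_iter),
            )
            if best is None or result[2][-1] < best[2][-1]:
                best = result
        centers, labels, trace, n_iter, converged = best
        order = np.argsort(centers, kind="stable")
        self.centers_ = centers[order]
        self.labels_ = np.argsort(order)[labels].reshape(img.shape)
        self.objective_ = float(trace[-1])
        self.objective_trace_ = list(map(float, trace))
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def predict(self, X):
        """Assign each pixel of ``X`` to its nearest fitted center."""
        img = check_image(X)
        return _assign(img.ravel(), self.centers_).reshape(img.shape)

    def to_model(self) -> ClusterModel:
        """Package the fitted attributes as a :class:`ClusterModel`."""
        return ClusterModel(
            centers=self.centers_,
            labels=self.labels_,
            objective=self.objective_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            objective_trace=self.objective_trace_,
        )


class KMeansSegmenter(_LloydSegmenter):
    """k-means intensity clustering (Lloyd iteration, member means).

    Parameters
    ----------
    k : int, default=3
        Number of clusters (air / parenchyma / dense tissue+tumor).
    tol : float, default=1e-6
        Convergence threshold on the maximum center shift.
    max_iter : int, default=300
    n_restarts : int, default=10
        Seeded restarts; the run with the lowest objective wins.
    random_state : int or None
    """

    _center_fn = staticmethod(np.mean)
    _objective_fn = staticmethod(lambda dev: float(np.sum(dev**2)))


class KMedianSegmenter(_LloydSegmenter):
    """k-median intensity clustering: centers are member medians and the
    objective is the sum of absolute deviations, making the fit robust to
    extreme intensities. Parameters as :class:`KMeansSegmenter`.
    """

    _center_fn = staticmethod(np.median)
    _objective_fn = staticmethod(lambda dev: float(np.sum(dev)))


def kmeans_segment(
    img,
    k: int = 3,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = None,
    n_restarts: int = 10,
) -> ClusterModel:
    """Segment ``img`` into ``k`` intensity clusters by k-means."""
    est = KMeansSegmenter(
        k=k, tol=tol, max_iter=max_iter, n_restarts=n_restarts, random_state=seed
    ).fit(img)
    return est.to_model()


def kmedian_segment(
    img,
    k: int = 3,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = None,
    n_restarts: int = 10,
) -> ClusterModel:
    """Segment ``img`` into ``k`` intensity clusters by k-median."""
    est = KMedianSegmenter(
        k=k, tol=tol, max_iter=max_iter, n_restarts=n_restarts, random_state=seed
    ).fit(img)
    return est.to_model()
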