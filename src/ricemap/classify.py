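"""Unsupervised classification of enhanced images and cluster merging.

The 3-band enhanced images are clustered with K-Means (Lloyd's algorithm,
k = 10 clusters, at most 20 iterations — the settings used operationally)
and clusters are then merged into thematic binary layers (rice / cropland /
forest) either from a user-supplied mapping informed by survey data or from
a documented centroid heuristic for unattended runs.

Lloyd's loop is implemented here rather than delegated, because the
pipeline contract pins details a library call leaves unspecified:
k-means++ seeding with an explicit seed, lowest-index tie-breaking for
equidistant points, farthest-point re-seeding of empty clusters, and a
recorded per-iteration inertia trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import kmeans_plusplus
from sklearn.utils.validation import check_is_fitted

from .grids import Grid2D, Unit, check_coregistered
from .temporal import EnhancedImage

CLASS_NAMES = ("water", "forest", "cropland", "early_rice", "middle_rice", "late_rice")


@dataclass
class ClusterMap:
    """Integer cluster labels on the grid plus centroids and final inertia."""

    labels: Grid2D            # Unit.LABEL; nodata where input invalid
    centroids: np.ndarray     # (k, 3) in (min, max, diff) band space
    inertia: float
    inertia_history: np.ndarray

    @property
    def k(self) -> int:
        return len(self.centroids)


@dataclass
class ClassLayer:
    """Binary presence mask for one thematic class."""

    mask: Grid2D              # values in {0, 1} on valid pixels
    class_name: str

    def __post_init__(self) -> None:
        valid = self.mask.valid_values()
        if valid.size and not np.isin(valid, (0, 1)).all():
            raise ValueError("class layer values must be 0 or 1")


class EnhancedImageKMeans(BaseEstimator, ClusterMixin):
    """K-Means (Lloyd) on (min, max, diff) feature vectors.

    Parameters
    ----------
    n_clusters : int, default 10
        Number of spectral clusters.
    max_iter : int, default 20
        Lloyd iteration cap.
    random_state : int, default 0
        Seed for k-means++ initialization; runs are deterministic given it.
    tol : float, default 0.0
        Early stop when assignments stabilise (tol reserved for centre
        motion; assignment stability is the primary criterion).

    Attributes
    ----------
    cluster_centers_ : (k, n_features) array
    labels_ : (n_samples,) array
    inertia_ : float
    inertia_history_ : per-iteration inertia, non-increasing
    n_iter_ : iterations run
    """

    def __init__(self, n_clusters: int = 10, max_iter: int = 20,
                 random_state: int = 0, tol: float = 0.0):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.random_state = random_state
        self.tol = tol

    # -- core Lloyd loop --------------------------------------------------
    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        n, _ = X.shape
        k = self.n_clusters
        if k < 1:
            raise ValueError(f"n_clusters must be >= 1, got {k}")
        if n < k:
            raise ValueError(f"need at least {k} samples, got {n}")

        rng = np.random.RandomState(self.random_state)
        centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=rng)

        labels = np.full(n, -1, dtype=int)
        history = []
        for it in range(self.max_iter):
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            new_labels = np.argmin(d2, axis=1)  # first minimum: lowest index wins ties
            inertia = float(d2[np.arange(n), new_labels].sum())
            history.append(inertia)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                members = X[labels == j]
                if len(members):
                    centers[j] = members.mean(axis=0)
                else:
                    # re-seed an empty cluster from the worst-fit point
                    farthest = int(np.argmax(d2[np.arange(n), labels]))
                    centers[j] = X[farthest]
                    labels[farthest] = j

        self.cluster_centers_ = centers
        self.labels_ = labels
        self.inertia_ = history[-1]
        self.inertia_history_ = np.asarray(history)
        self.n_iter_ = len(history)
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


def kmeans_classify(image: EnhancedImage, k: int = 10, max_iter: int = 20,
                    seed: int = 0) -> ClusterMap:
    """Cluster an enhanced image's valid pixels; nodata stays unlabeled."""
    feats = image.features()
    est = EnhancedImageKMeans(n_clusters=k, max_iter=max_iter, random_state=seed)
    est.fit(feats)
    labels = np.full(image.shape, -1, dtype=int)
    valid = image.valid_mask
    labels[valid] = est.labels_
    grid = Grid2D(labels, Unit.LABEL, image.band_min.transform,
                  nodata_mask=~valid)
    return ClusterMap(grid, est.cluster_centers_, est.inertia_,
                      est.inertia_history_)


def merge_clusters(clusters: ClusterMap,
                   mapping: dict[int, str]) -> list[ClassLayer]:
    """Merge clusters into one binary layer per thematic class.

    ``mapping`` must cover every cluster id; ids mapped to ``"other"``
    appear in no layer.
    """
    missing = set(range(clusters.k)) - set(mapping)
    if missing:
        raise KeyError(f"mapping missing cluster ids {sorted(missing)}")
    bad = {v for v in mapping.values() if v != "other" and v not in CLASS_NAMES}
    if bad:
        raise KeyError(f"unknown class names {sorted(bad)}")
    labels = clusters.labels
    layers = []
    for name in CLASS_NAMES:
        ids = [cid for cid, cls in mapping.items() if cls == name]
        if not ids:
            continue
        mask = np.isin(labels.values, ids).astype(np.int16)
        mask[labels.nodata_mask] = 0
        layers.append(ClassLayer(labels.with_values(mask), name))
    return layers


def auto_assign_clusters(clusters: ClusterMap, product: str,
                         rice_class: str = "early_rice") -> dict[int, str]:
    """Heuristic centroid-based cluster-to-class mapping for unattended runs.

    For a rice-enhanced product a cluster is rice when its difference-band
    centroid lies above the across-centroid midpoint *and* its minimum-band
    centroid lies below the midpoint (flooded transplanting then canopy
    peak).  For the cropland image, high difference means cropland
    (bare-winter/green-summer) and high maximum with low difference means
    forest (evergreen).  This default should be overridden with a
    survey-informed mapping when reference data exist.
    """
    if product not in ("rice_enhanced", "cropland_image"):
        raise ValueError(f"unknown product {product!r}")
    c = clusters.centroids
    cmin, cmax, cdiff = c[:, 0], c[:, 1], c[:, 2]

    def midpoint(v: np.ndarray) -> float:
        return (float(v.min()) + float(v.max())) / 2.0

    mapping: dict[int, str] = {}
    if len(c) == 1 or np.ptp(cdiff) == 0:
        return {i: "other" for i in range(len(c))}
    mid_diff, mid_min, mid_max = midpoint(cdiff), midpoint(cmin), midpoint(cmax)
    for i in range(len(c)):
        if product == "rice_enhanced":
            is_rice = cdiff[i] > mid_diff and cmin[i] < mid_min
            mapping[i] = rice_class if is_rice else "other"
        else:
            if cdiff[i] > mid_diff:
                mapping[i] = "cropland"
            elif cmax[i] > mid_max and cdiff[i] <= mid_diff:
                mapping[i] = "forest"
            else:
                mapping[i] = "other"
    return mapping
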