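"""Repertoire clustering: density-based on (peak frequency, duration) and
contour-shape k-means with elbow selection of k.

Density clustering standardizes the two features, picks an epsilon radius
from the knee of the sorted k-th-nearest-neighbor distance curve, and runs
DBSCAN with a large core-point minimum (default 150) so only substantial
call populations form clusters.  Cluster quality is summarized by the
silhouette coefficient computed on clustered (non-outlier) points.

Contour k-means resamples each call's frequency contour to a fixed length,
z-scores contour / duration / peak-frequency feature blocks with equal
block weights, and selects k by the largest second difference of the
inertia curve (capped at ``max_k``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import DBSCAN, KMeans
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from usv44.calltable_io import CallContour, CallRecord

DEFAULT_MIN_PTS = 150
DEFAULT_EPS = 0.14
CONTOUR_RESAMPLE_POINTS = 32


def standardize_features(records_or_matrix, feature_names: Sequence[str] = ("peak_frequency", "duration")):
    """Z-score features over the dataset; returns ``(standardized, raw)``.

    Accepts either a sequence of :class:`CallRecord` (features taken per
    ``feature_names``) or a 2-D numeric array.  A zero-variance feature is
    an error naming the feature.
    """
    if isinstance(records_or_matrix, np.ndarray):
        raw = np.asarray(records_or_matrix, dtype=float)
        names = [f"column_{i}" for i in range(raw.shape[1])] if raw.ndim == 2 else []
    else:
        records = list(records_or_matrix)
        raw = np.array([[getattr(r, name) for name in feature_names] for r in records], dtype=float)
        names = list(feature_names)
    if raw.ndim != 2 or raw.shape[0] < 2:
        raise ValueError("need at least 2 observations of 2-D features")
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"zero-variance feature: {names[j]}")
    return (raw - mu) / sd, raw


@dataclass
class EpsEstimate:
    """Knee of the sorted k-distance curve, with a +-30% search range."""

    knee: float
    low: float
    high: float
    k_distances: np.ndarray = field(repr=False, default=None)


def estimate_eps(features: np.ndarray, k: int = DEFAULT_MIN_PTS) -> EpsEstimate:
    """Heuristic epsilon from the sorted k-th-nearest-neighbor distances.

    The knee is the point of the ascending curve farthest from the chord
    joining its endpoints (maximum-curvature proxy).
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)  # +1: self-distance column
    dist, _ = nn.kneighbors(X)
    kdist = np.sort(dist[:, k])
    if kdist[-1] <= 0 or kdist[-1] - kdist[0] <= 1e-12 * max(kdist[-1], 1.0):
        raise ValueError("degenerate distances: k-distance curve is flat")
    # distance of each curve point from the first->last chord
    x = np.arange(n, dtype=float)
    dx, dy = x[-1] - x[0], kdist[-1] - kdist[0]
    norm = np.hypot(dx, dy)
    offset = np.abs(dy * (x - x[0]) - dx * (kdist - kdist[0])) / norm
    knee = float(kdist[int(np.argmax(offset))])
    if knee <= 0:
        raise ValueError("degenerate distances: knee at zero distance")
    return EpsEstimate(knee=knee, low=0.7 * knee, high=1.3 * knee, k_distances=kdist)


@dataclass
class ClusterStats:
    size: int
    mean_peak_frequency: float
    mean_duration: float


@dataclass
class ClusterResult:
    labels: np.ndarray
    eps: float
    min_pts: int
    silhouette: Optional[float]
    cluster_stats: dict[int, ClusterStats]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_stats)

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.labels == -1))

    def to_dict(self) -> dict:
        return {
            "eps": self.eps,
            "min_pts": self.min_pts,
            "silhouette": self.silhouette,
            "n_clusters": self.n_clusters,
            "n_outliers": self.n_outliers,
            "clusters": {
                str(k): {
                    "size": s.size,
                    "mean_peak_frequency_hz": s.mean_peak_frequency,
                    "mean_duration_s": s.mean_duration,
                }
                for k, s in self.cluster_stats.items()
            },
        }


def dbscan_cluster(
    features: np.ndarray,
    eps: float,
    min_pts: int = DEFAULT_MIN_PTS,
    raw_features: Optional[np.ndarray] = None,
) -> ClusterResult:
    """Density clustering of standardized features; outliers labeled -1.

    Per-cluster means are computed on ``raw_features`` (unstandardized
    ``(peak_frequency, duration)`` columns) when provided, else on
    ``features``.  Silhouette uses clustered points only and is ``None``
    with fewer than two clusters.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    X = np.asarray(features, dtype=float)
    raw = X if raw_features is None else np.asarray(raw_features, dtype=float)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(X)
    stats: dict[int, ClusterStats] = {}
    for lab in sorted(set(labels.tolist()) - {-1}):
        members = raw[labels == lab]
        stats[int(lab)] = ClusterStats(
            size=int(members.shape[0]),
            mean_peak_frequency=float(members[:, 0].mean()),
            mean_duration=float(members[:, 1].mean()),
        )
    sil = None
    core = labels != -1
    if len(stats) >= 2 and np.unique(labels[core]).size >= 2:
        sil = float(silhouette_score(X[core], labels[core]))
    return ClusterResult(labels=labels, eps=float(eps), min_pts=int(min_pts), silhouette=sil, cluster_stats=stats)


def cluster_records(
    records: Sequence[CallRecord],
    eps: Optional[float] = None,
    min_pts: int = DEFAULT_MIN_PTS,
) -> ClusterResult:
    """Convenience: standardize (peak frequency, duration) of records, pick
    epsilon from the k-distance knee unless given, run DBSCAN."""
    X, raw = standardize_features(records)
    if eps is None:
        eps = estimate_eps(X, k=min_pts).knee
    return dbscan_cluster(X, eps=eps, min_pts=min_pts, raw_features=raw)


def resample_contour(contour: CallContour, n_points: int = CONTOUR_RESAMPLE_POINTS) -> np.ndarray:
    """Linearly resample a contour's frequencies onto ``n_points`` equally
    spaced times across its span."""
    if len(contour) < 2:
        raise ValueError("contour must have at least 2 points")
    grid = np.linspace(contour.times[0], contour.times[-1], n_points)
    return np.interp(grid, contour.times, contour.frequencies)


@dataclass
class KMeansResult:
    labels: np.ndarray
    k: int
    inertia_curve: dict[int, float]
    embedding: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "inertia_curve": {str(k): v for k, v in self.inertia_curve.items()},
            "labels": self.labels.tolist(),
        }


def _block_standardize(block: np.ndarray, weight: float) -> np.ndarray:
    """Z-score columns, then scale so the whole block carries ``weight``
    total variance regardless of its column count."""
    mu = block.mean(axis=0)
    sd = block.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (block - mu) / sd
    return z * np.sqrt(weight / block.shape[1])


def contour_feature_matrix(
    contours: Sequence[CallContour],
    durations: Sequence[float],
    peak_frequencies: Sequence[float],
    n_points: int = CONTOUR_RESAMPLE_POINTS,
) -> np.ndarray:
    """Fixed-length contour-shape + duration + peak-frequency features with
    equal per-block weights."""
    shape = np.array([resample_contour(c, n_points) for c in contours], dtype=float)
    dur = np.asarray(durations, dtype=float).reshape(-1, 1)
    pf = np.asarray(peak_frequencies, dtype=float).reshape(-1, 1)
    if not shape.shape[0] == dur.shape[0] == pf.shape[0]:
        raise ValueError("contours, durations, peak_frequencies must align")
    return np.hstack(
        [
            _block_standardize(shape, 1.0),
            _block_standardize(dur, 1.0),
            _block_standardize(pf, 1.0),
        ]
    )


def choose_k_elbow(inertia_curve: dict[int, float], max_k: int) -> int:
    """Largest second forward difference of inertia over k; degenerate
    (already near-zero or flat) curves fall back to k=1."""
    ks = sorted(inertia_curve)
    inertias = np.array([inertia_curve[k] for k in ks])
    scale = max(inertias[0], 1e-30)
    if inertias[0] <= 1e-12 or (inertias[0] - inertias[-1]) <= 1e-9 * scale:
        return 1
    if len(ks) < 3:
        return min(2, max_k)
    second_diff = inertias[:-2] - 2 * inertias[1:-1] + inertias[2:]
    return ks[1 + int(np.argmax(second_diff))]


def contour_kmeans(
    contours: Sequence[CallContour],
    durations: Sequence[float],
    peak_frequencies: Sequence[float],
    max_k: int = 4,
    n_init: int = 10,
    seed: int = 0,
    embed: bool = False,
) -> KMeansResult:
    """Contour-based k-means with elbow-selected k (seeded, reproducible).

    The optional 2-D embedding (UMAP) is a visualization by-product only;
    labels never depend on it.
    """
    X = contour_feature_matrix(contours, durations, peak_frequencies)
    if X.shape[0] < max_k:
        raise ValueError(f"need at least max_k={max_k} calls with contours, got {X.shape[0]}")
    inertia_curve: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in range(1, max_k + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        inertia_curve[k] = float(km.inertia_)
        fits[k] = km
    k = choose_k_elbow(inertia_curve, max_k)
    labels = fits[k].labels_.copy()
    embedding = None
    if embed:
        import umap  # heavy import; optional cosmetic output

        embedding = umap.UMAP(n_components=2, random_state=seed).fit_transform(X)
    return KMeansResult(labels=labels, k=k, inertia_curve=inertia_curve, embedding=embedding)
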