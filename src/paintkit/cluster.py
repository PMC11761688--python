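"""DBSCAN nanocluster analysis and nearest-neighbor density mapping.

Localization patches are segmented with DBSCAN (defaults eps = 0.3 in the
coordinate units — interpreted as um for nm-scale pipelines, i.e. 300 nm —
and min_pts = 5, self included). Per-cluster morphology is summarized by
convex-hull area, covariance-based axis lengths, and eccentricity; the
primary eccentricity output is the minor/major axis ratio in [0, 1] (the
standard sqrt(1 - ratio^2) form is also emitted). The nearest-neighbor
analysis assigns each clustered localization a local density: the count of
co-cluster members within a radius scaled to the cluster's mean NN
distance, with an optional highlight mask at 5x the cluster mean NN
distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree
from sklearn.cluster import DBSCAN as _SkDBSCAN

DEFAULT_EPS = 0.3          # coordinate units (um for the nm-scale pipeline)
DEFAULT_MIN_PTS = 5
DEFAULT_RADIUS_SCALE = 1.0
DEFAULT_HIGHLIGHT_K = 5.0

NOISE = -1


def dbscan(points: np.ndarray, eps: float = DEFAULT_EPS, min_pts: int = DEFAULT_MIN_PTS) -> np.ndarray:
    """Density-based clustering; returns per-point labels, -1 for noise.

    A core point has at least ``min_pts`` neighbors within ``eps``
    (itself included); clusters are maximal density-connected sets. Labels
    of non-noise points are contiguous integers from 0 in order of first
    appearance.
    """
    points = np.asarray(points, dtype=float)
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    if len(points) == 0:
        return np.empty(0, dtype=int)
    labels = _SkDBSCAN(eps=eps, min_samples=min_pts).fit(points).labels_
    return _relabel_by_first_appearance(labels)


def _relabel_by_first_appearance(labels: np.ndarray) -> np.ndarray:
    out = np.full(len(labels), NOISE, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == NOISE:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


@dataclass
class ClusterResult:
    """Per-localization labels plus per-cluster morphology statistics.

    ``per_cluster`` columns: label, n_members, area (squared coordinate
    units; um^2 when coordinates are um), major_axis, minor_axis (4 sigma
    full widths), axis_ratio (minor/major in [0, 1]), eccentricity
    (sqrt(1 - axis_ratio^2)), mean_nn_distance.
    """

    labels: np.ndarray
    per_cluster: pd.DataFrame
    n_clusters: int
    fraction_clustered: float


def nn_distances(points: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to its nearest distinct point."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points for nearest-neighbor distances")
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return d[:, 1]


def _hull_area(pts: np.ndarray) -> float:
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2D: volume is the area
    except QhullError:  # collinear members
        return 0.0


def cluster_metrics(points: np.ndarray, labels: np.ndarray) -> ClusterResult:
    """Morphology per DBSCAN cluster.

    Axis lengths are 4 sqrt(eigenvalues) of the member coordinate
    covariance (full widths at ~2 sigma); clusters with < 3 members or a
    degenerate covariance get area 0 and NaN eccentricity.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cluster_ids = np.unique(labels[labels != NOISE])
    rows = []
    for cid in cluster_ids:
        members = points[labels == cid]
        n = len(members)
        area = _hull_area(members)
        if n >= 2:
            cov = np.cov(members.T)
            eig = np.sort(np.linalg.eigvalsh(cov))
            eig = np.clip(eig, 0.0, None)
            minor, major = 4.0 * np.sqrt(eig)
        else:
            minor = major = 0.0
        if n >= 3 and major > 0:
            ratio = minor / major
            ecc = float(np.sqrt(max(1.0 - ratio**2, 0.0)))
        else:
            ratio, ecc = np.nan, np.nan
        mean_nn = float(np.mean(nn_distances(members))) if n >= 2 else np.nan
        rows.append((cid, n, area, major, minor, ratio, ecc, mean_nn))
    per_cluster = pd.DataFrame(
        rows,
        columns=["label", "n_members", "area", "major_axis", "minor_axis",
                 "axis_ratio", "eccentricity", "mean_nn_distance"],
    )
    n_total = len(labels)
    frac = float(np.sum(labels != NOISE) / n_total) if n_total else 0.0
    return ClusterResult(labels, per_cluster, len(cluster_ids), frac)


@dataclass
class DensityMap:
    """Per-localization NN distance and scaled-radius neighbor counts.

    ``neighbor_count`` counts co-cluster members within
    ``radius_scale x (cluster mean NN distance)``, self excluded; NaN for
    noise points. ``highlight`` marks members whose own NN distance is at
    most ``k x`` their cluster's mean NN distance.
    """

    nn_distance: np.ndarray
    neighbor_count: np.ndarray
    cluster_mean_nn: np.ndarray  # per-point, NaN for noise
    highlight: Optional[np.ndarray] = None


def local_density_map(
    points: np.ndarray, labels: np.ndarray, radius_scale: float = DEFAULT_RADIUS_SCALE
) -> DensityMap:
    """Local density around each clustered localization.

    For each cluster the mean NN distance D_c of its members sets the query
    radius ``radius_scale x D_c``; each member's density is the number of
    co-cluster members within that radius (self excluded).
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(points)
    nn_all = np.full(n, np.nan)
    counts = np.full(n, np.nan)
    mean_nn = np.full(n, np.nan)
    for cid in np.unique(labels[labels != NOISE]):
        idx = np.flatnonzero(labels == cid)
        members = points[idx]
        if len(members) < 2:
            continue
        d = nn_distances(members)
        nn_all[idx] = d
        d_c = float(d.mean())
        mean_nn[idx] = d_c
        tree = cKDTree(members)
        neigh = tree.query_ball_point(members, r=radius_scale * d_c)
        counts[idx] = np.array([len(lst) - 1 for lst in neigh], dtype=float)
    return DensityMap(nn_all, counts, mean_nn)


def highlight_threshold(density_map: DensityMap, k: float = DEFAULT_HIGHLIGHT_K) -> np.ndarray:
    """Mask of members whose NN distance <= k x their cluster mean NN distance."""
    with np.errstate(invalid="ignore"):
        mask = density_map.nn_distance <= k * density_map.cluster_mean_nn
    mask = np.where(np.isnan(density_map.cluster_mean_nn), False, mask)
    density_map.highlight = mask.astype(bool)
    return density_map.highlight
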