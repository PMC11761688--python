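"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (O(n^2) scans, direct
density-reachability expansion) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import numpy as np


def pairwise_distances(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def nn_distances_bruteforce(points: np.ndarray) -> np.ndarray:
    d = pairwise_distances(points)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def neighbor_counts_bruteforce(points: np.ndarray, radius: float) -> np.ndarray:
    d = pairwise_distances(points)
    np.fill_diagonal(d, np.inf)
    return (d <= radius).sum(axis=1)


def dbscan_bruteforce(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Index-ordered density-reachability expansion; -1 = noise."""
    n = len(points)
    d = pairwise_distances(points)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]  # self included
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cluster
        frontier = [i]
        while frontier:
            j = frontier.pop(0)
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        frontier.append(k)
        cluster += 1
    return labels


def clusterings_equivalent(
    labels_a: np.ndarray, labels_b: np.ndarray, points: np.ndarray,
    eps: float, min_pts: int,
) -> bool:
    """Density-clustering equality up to relabeling and border ambiguity.

    Noise sets must match exactly, core points must induce the same
    partition, and every border point must sit within eps of a core point
    of its assigned cluster in both labelings (border points reachable from
    two clusters may legitimately differ).
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    d = pairwise_distances(points)
    n_neighbors = (d <= eps).sum(axis=1)
    core = n_neighbors >= min_pts

    if not np.array_equal(labels_a == -1, labels_b == -1):
        return False
    # core partition must agree up to relabeling
    mapping: dict[int, int] = {}
    for i in np.flatnonzero(core):
        a, b = labels_a[i], labels_b[i]
        if a == -1 or b == -1:
            return False
        if a in mapping:
            if mapping[a] != b:
                return False
        elif b in mapping.values():
            return False
        else:
            mapping[a] = b
    # border points: must be eps-adjacent to a core member of their cluster
    for labels in (labels_a, labels_b):
        border = (~core) & (labels != -1)
        for i in np.flatnonzero(border):
            same = (labels == labels[i]) & core
            if not np.any(d[i, same] <= eps):
                return False
    return True


def exponential_mean_mle(samples: np.ndarray) -> float:
    return float(np.mean(samples))


def hull_area_shoelace(points: np.ndarray) -> float:
    """Convex-hull area via gift wrapping + shoelace (small n only)."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return 0.0
    # gift wrapping
    start = np.lexsort((pts[:, 1], pts[:, 0]))[0]
    hull = [start]
    while True:
        p = hull[-1]
        q = (p + 1) % len(pts)
        for r in range(len(pts)):
            u, v = pts[q] - pts[p], pts[r] - pts[p]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0 and
                             np.linalg.norm(pts[r] - pts[p]) > np.linalg.norm(pts[q] - pts[p])):
                q = r
        if q == start:
            break
        hull.append(q)
        if len(hull) > len(pts):
            return 0.0
    poly = pts[hull]
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
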