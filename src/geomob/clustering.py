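"""Per-user density-based clustering of event coordinates.

DBSCAN in raw (lon, lat) degree space with a neighbourhood radius of
eps = 0.5 coordinate units (roughly the Greater London metropolitan scale)
and MinPts set to 2% of the user's event count, floored at 2.  The point
itself counts toward its own neighbourhood (the standard |N_eps(p)| >=
MinPts convention).  Cluster ids follow the order in which the first core
point of each cluster appears in the input, so labelling is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

DEFAULT_EPS = 0.5
DEFAULT_MIN_FRACTION = 0.02
MIN_PTS_FLOOR = 2


@dataclass
class ClusterAssignment:
    """DBSCAN output for one user: per-event labels plus the parameters used."""

    labels: np.ndarray  # -1 noise, else 0..n_clusters-1
    n_clusters: int
    eps: float
    min_pts: int
    core_mask: np.ndarray = None

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def min_points_for_user(n_events: int, fraction: float = DEFAULT_MIN_FRACTION) -> int:
    """MinPts = max(2, round-half-up(fraction * n_events))."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    return max(MIN_PTS_FLOOR, int(np.floor(fraction * n_events + 0.5)))


def dbscan(points: np.ndarray, eps: float = DEFAULT_EPS,
           min_pts: int = None) -> ClusterAssignment:
    """Classic DBSCAN over (lon, lat) points with Euclidean degree distance.

    ``min_pts`` defaults to the 2%-of-events rule.  Empty input yields zero
    clusters.  Labels are relabelled to first-appearance order so output is
    independent of backend label conventions.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts is None:
        min_pts = min_points_for_user(max(len(points), 1))
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    if len(points) == 0:
        return ClusterAssignment(labels=np.empty(0, dtype=int), n_clusters=0,
                                 eps=eps, min_pts=min_pts,
                                 core_mask=np.empty(0, dtype=bool))
    model = DBSCAN(eps=eps, min_samples=min_pts, metric="euclidean").fit(points)
    raw = model.labels_
    core = np.zeros(len(points), dtype=bool)
    core[model.core_sample_indices_] = True
    # relabel clusters in order of first core point appearance
    mapping = {}
    for i in np.flatnonzero(core):
        if raw[i] not in mapping:
            mapping[raw[i]] = len(mapping)
    labels = np.array([mapping[l] if l != -1 else -1 for l in raw], dtype=int)
    return ClusterAssignment(labels=labels, n_clusters=len(mapping),
                             eps=eps, min_pts=min_pts, core_mask=core)


def cluster_centroids(points: np.ndarray, assignment: ClusterAssignment) -> np.ndarray:
    """Arithmetic mean (lon, lat) of each cluster's members, noise excluded.

    Returns an (n_clusters, 2) array in cluster-id order; empty for zero
    clusters.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) != len(assignment.labels):
        raise ValueError("points and assignment length mismatch")
    out = np.empty((assignment.n_clusters, 2))
    for c in range(assignment.n_clusters):
        out[c] = points[assignment.labels == c].mean(axis=0)
    return out
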