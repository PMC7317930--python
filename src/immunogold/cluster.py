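"""Cluster statistics for immunogold point patterns.

Particles within one profile are grouped by single-linkage: connected
components of the graph joining pairs closer than ``link_distance_nm``
centre-to-centre.  Components with fewer than ``min_cluster_size`` members
(default three) are reported as scattered, matching the min-3 membership
rule; each retained cluster is characterised by its member count, the area
of the convex hull of its members, its centroid and the distance to the
nearest other cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, cKDTree


@dataclass(frozen=True)
class ClusterParams:
    link_distance_nm: float = 50.0
    min_cluster_size: int = 3

    def __post_init__(self) -> None:
        if self.link_distance_nm <= 0:
            raise ValueError("link_distance_nm must be positive")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class ClusterRecord:
    cluster_id: int
    member_indices: tuple[int, ...]
    size: int
    hull_area_nm2: float
    centroid_nm: tuple[float, float]
    nearest_cluster_distance_nm: Optional[float] = None  # None when < 2 clusters


def hull_area(points: np.ndarray) -> float:
    """Exact convex-hull area in nm^2; zero for collinear members."""
    points = np.asarray(points, float)
    if len(points) < 3:
        raise ValueError("hull area needs at least 3 points")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        return 0.0
    return float(ConvexHull(points).volume)  # 2-D "volume" is the area


def link_clusters(
    xy: np.ndarray | pd.DataFrame, params: ClusterParams = ClusterParams()
) -> tuple[list[ClusterRecord], np.ndarray]:
    """Single-linkage grouping; returns cluster records and scattered indices.

    Cluster ids follow the lexicographic (x, y) order of cluster centroids,
    so the labelling is deterministic and independent of input order.
    """
    if isinstance(xy, pd.DataFrame):
        xy = xy[["x_nm", "y_nm"]].to_numpy(float)
    xy = np.asarray(xy, float)
    n = len(xy)
    if n == 0:
        return [], np.array([], dtype=int)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(params.link_distance_nm, output_type="ndarray")
    if len(pairs):
        data = np.ones(len(pairs))
        graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    _, labels = connected_components(graph, directed=False)

    clusters = []
    scattered = []
    for comp in np.unique(labels):
        idx = np.flatnonzero(labels == comp)
        if len(idx) < params.min_cluster_size:
            scattered.extend(idx.tolist())
            continue
        pts = xy[idx]
        centroid = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
        area = hull_area(pts) if len(idx) >= 3 else 0.0
        clusters.append(
            ClusterRecord(
                cluster_id=-1,
                member_indices=tuple(int(i) for i in idx),
                size=len(idx),
                hull_area_nm2=area,
                centroid_nm=centroid,
            )
        )
    clusters.sort(key=lambda c: c.centroid_nm)
    for i, c in enumerate(clusters):
        c.cluster_id = i
    nearest_cluster_distance(clusters)
    return clusters, np.array(sorted(scattered), dtype=int)


def nearest_cluster_distance(clusters: Sequence[ClusterRecord]) -> list[Optional[float]]:
    """Centroid-to-centroid distance to the closest other cluster (in place)."""
    k = len(clusters)
    if k < 2:
        for c in clusters:
            c.nearest_cluster_distance_nm = None
        return [None] * k
    cents = np.array([c.centroid_nm for c in clusters])
    d = np.hypot(
        cents[:, None, 0] - cents[None, :, 0], cents[:, None, 1] - cents[None, :, 1]
    )
    np.fill_diagonal(d, np.inf)
    nearest = d.min(axis=1)
    for c, dist in zip(clusters, nearest):
        c.nearest_cluster_distance_nm = float(dist)
    return [float(x) for x in nearest]


def clusters_frame(clusters: Sequence[ClusterRecord], profile_id: str = "") -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "profile_id": [profile_id] * len(clusters),
            "cluster_id": [c.cluster_id for c in clusters],
            "size": [c.size for c in clusters],
            "hull_area_nm2": [c.hull_area_nm2 for c in clusters],
            "centroid_x_nm": [c.centroid_nm[0] for c in clusters],
            "centroid_y_nm": [c.centroid_nm[1] for c in clusters],
            "nearest_cluster_distance_nm": [
                np.nan
                if c.nearest_cluster_distance_nm is None
                else c.nearest_cluster_distance_nm
                for c in clusters
            ],
        }
    )
    return df.astype(
        {
            "profile_id": str,
            "cluster_id": int,
            "size": int,
            "hull_area_nm2": float,
            "centroid_x_nm": float,
            "centroid_y_nm": float,
            "nearest_cluster_distance_nm": float,
        }
    )


def composition_histogram(
    cluster_sizes: Sequence[int],
    pooled_area_um2: float,
    reference_area_um2: float = 140.0,
    *,
    area_tolerance: float = 0.05,
) -> dict:
    """Cluster-size histogram pooled over a fixed reference membrane area.

    The pooled profile area must match the configured reference area within
    the tolerance, so compositions are comparable across conditions.
    """
    if abs(pooled_area_um2 - reference_area_um2) > area_tolerance * reference_area_um2:
        raise ValueError(
            f"pooled area {pooled_area_um2:.2f} um^2 outside "
            f"{reference_area_um2:.2f} +/- {100 * area_tolerance:.0f}%; "
            "re-sample profiles to match the reference area"
        )
    sizes = np.asarray(list(cluster_sizes), dtype=int)
    total = len(sizes)
    if total == 0:
        return {
            "counts": {},
            "percentages": {},
            "total_clusters": 0,
            "size_range": None,
            "pooled_area_um2": pooled_area_um2,
        }
    values, counts = np.unique(sizes, return_counts=True)
    return {
        "counts": {int(v): int(c) for v, c in zip(values, counts)},
        "percentages": {int(v): 100.0 * c / total for v, c in zip(values, counts)},
        "total_clusters": int(total),
        "size_range": (int(sizes.min()), int(sizes.max())),
        "pooled_area_um2": pooled_area_um2,
    }
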