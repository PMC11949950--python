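"""Mapper-based topological data analysis (the contrast method).

Pipeline: per-volume Euclidean distances -> symmetrized k-nearest-neighbour
graph -> all-pairs geodesic (shortest-path) distances -> classical
2-D multidimensional scaling -> overlapping 2-D binning at a given
resolution -> single-linkage partial clustering within each bin (cut at the
first empty bin of the linkage-distance histogram) -> shape graph linking
clusters from different bins that share volumes.

Every step is deterministic: classical (eigendecomposition) MDS with a
fixed sign convention, stable tie-breaks in the kNN construction, and an
internal canonical (lexicographic) ordering of volumes so that all outputs
are exactly invariant to row permutations of the input — the shape graph
uses no temporal information.
"""
from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

from .datatypes import MapperConfig, MapperGraph, MapperNode, RoiTimeSeries
from .errors import DegenerateStatisticError, ValidityError

__all__ = [
    "geodesic_filter",
    "overlapping_bins",
    "partial_cluster",
    "shape_graph",
    "run_mapper",
    "high_degree_proportion",
    "condition_anova",
]

logger = logging.getLogger(__name__)


def _canonical_order(data: np.ndarray) -> np.ndarray:
    """Lexicographic row order (column 0 most significant)."""
    return np.lexsort(tuple(data.T[::-1]))


def _knn_geodesics(data: np.ndarray, k: int) -> np.ndarray:
    """All-pairs shortest-path distances over the symmetrized kNN graph.

    Disconnected components are bridged by the single shortest
    inter-component Euclidean edge (repeated until connected, logged).
    """
    t = data.shape[0]
    d_euc = squareform(pdist(data))
    order = np.argsort(d_euc, axis=1, kind="stable")
    rows = np.repeat(np.arange(t), k)
    cols = order[:, 1:k + 1].ravel()          # skip self (distance 0)
    w = d_euc[rows, cols]
    graph = coo_matrix((w, (rows, cols)), shape=(t, t)).tocsr()
    graph = graph.maximum(graph.T)            # symmetrize (union of edges)
    n_comp, labels = connected_components(graph, directed=False)
    while n_comp > 1:
        best = (np.inf, -1, -1)
        for c in range(1, n_comp):
            a = np.flatnonzero(labels == 0)
            b = np.flatnonzero(labels == c)
            sub = d_euc[np.ix_(a, b)]
            i, j = np.unravel_index(np.argmin(sub), sub.shape)
            if sub[i, j] < best[0]:
                best = (sub[i, j], int(a[i]), int(b[j]))
        dist, i, j = best
        logger.info("kNN graph disconnected; bridging %d-%d (d=%.4g)",
                    i, j, dist)
        graph = graph.tolil()
        graph[i, j] = graph[j, i] = dist
        graph = graph.tocsr()
        n_comp, labels = connected_components(graph, directed=False)
    return shortest_path(graph, method="D", directed=False)


def _classical_mds(d: np.ndarray, n_dim: int = 2) -> np.ndarray:
    """Deterministic classical MDS: double-centred squared distances,
    eigendecomposition, axes ordered by eigenvalue, each axis sign-fixed so
    its largest-magnitude coordinate is positive."""
    t = d.shape[0]
    d2 = d ** 2
    j = np.eye(t) - np.full((t, t), 1.0 / t)
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(0.5 * (b + b.T))
    idx = np.argsort(w)[::-1][:n_dim]
    coords = v[:, idx] * np.sqrt(np.clip(w[idx], 0.0, None))
    for a in range(coords.shape[1]):
        col = coords[:, a]
        peak = col[np.argmax(np.abs(col))]
        if peak < 0:
            coords[:, a] = -col
    return coords


def geodesic_filter(x, config: MapperConfig) -> np.ndarray:
    """T x 2 embedding of the volumes: kNN geodesic distances + classical MDS.

    Accepts a :class:`RoiTimeSeries` or a plain (T, N) array.  Volumes are
    processed internally in canonical (lexicographic) order and the
    embedding is returned in the original row order, making the result
    exactly permutation-invariant.
    """
    data = x.data if isinstance(x, RoiTimeSeries) else np.asarray(x, dtype=float)
    t = data.shape[0]
    if t < config.k_neighbors + 1:
        raise ValidityError(
            f"need T >= k+1 = {config.k_neighbors + 1} volumes, got {t}")
    order = _canonical_order(data)
    geo = _knn_geodesics(data[order], config.k_neighbors)
    coords = _classical_mds(geo, n_dim=2)
    out = np.empty_like(coords)
    out[order] = coords
    return out


def overlapping_bins(embedding: np.ndarray,
                     config: MapperConfig) -> Dict[Tuple[int, int], np.ndarray]:
    """Overlapping resolution x resolution cover of the embedding.

    Axis-aligned rectangles tile the bounding box; each is enlarged
    symmetrically so adjacent bins share ``overlap_fraction`` of the base
    width.  A volume belongs to every bin containing it; with zero overlap
    a point on a shared edge belongs to the lower-index bin.  Only
    non-empty bins are returned.
    """
    emb = np.asarray(embedding, dtype=float)
    if emb.ndim != 2 or emb.shape[1] != 2:
        raise ValidityError("embedding must be T x 2")
    res = config.resolution
    half = 0.5 * config.overlap_fraction
    members_by_axis: List[List[np.ndarray]] = []
    for axis in range(2):
        v = emb[:, axis]
        lo, hi = v.min(), v.max()
        width = (hi - lo) / res if hi > lo else 1.0
        axis_members = []
        for i in range(res):
            left = lo + (i - half) * width
            right = lo + (i + 1 + half) * width
            # outermost edges unbounded so rounding never drops extremes
            inside = np.ones_like(v, dtype=bool) if i == res - 1 \
                else (v <= right)
            if i > 0:
                inside = inside & (v > left)
            axis_members.append(inside)
        members_by_axis.append(axis_members)
    bins: Dict[Tuple[int, int], np.ndarray] = {}
    for ix in range(res):
        mx = members_by_axis[0][ix]
        if not mx.any():
            continue
        for iy in range(res):
            both = mx & members_by_axis[1][iy]
            if both.any():
                bins[(ix, iy)] = np.flatnonzero(both)
    return bins


def _cluster_one_bin(points: np.ndarray, histogram_bins: int) -> np.ndarray:
    """Single-linkage labels within one bin, cut at the first empty bin of
    the linkage-distance histogram (standard Mapper heuristic)."""
    m = points.shape[0]
    if m == 1:
        return np.zeros(1, dtype=np.int64)
    z = linkage(pdist(points), method="single")
    heights = z[:, 2]
    counts, edges = np.histogram(heights, bins=histogram_bins)
    empty = np.flatnonzero(counts == 0)
    if empty.size == 0:
        return np.zeros(m, dtype=np.int64)     # no gap: one cluster
    cutoff = edges[empty[0]]
    return fcluster(z, t=cutoff, criterion="distance").astype(np.int64) - 1


def partial_cluster(bins: Mapping[Tuple[int, int], np.ndarray],
                    data: np.ndarray,
                    config: MapperConfig) -> List[MapperNode]:
    """Cluster each bin's members on ORIGINAL-space Euclidean distances.

    Returns one :class:`MapperNode` per (bin, cluster); member sets within
    one bin are disjoint.
    """
    data = np.asarray(data, dtype=float)
    nodes: List[MapperNode] = []
    node_id = 0
    for bin_id in sorted(bins):
        members = np.asarray(bins[bin_id], dtype=np.int64)
        labels = _cluster_one_bin(data[members], config.cluster_histogram_bins)
        for lab in np.unique(labels):
            nodes.append(MapperNode(node_id=node_id, bin_id=bin_id,
                                    members=members[labels == lab]))
            node_id += 1
    return nodes


def shape_graph(nodes: Sequence[MapperNode]) -> MapperGraph:
    """Link clusters from different bins sharing at least one volume."""
    owners: Dict[int, List[int]] = {}
    for node in nodes:
        for vol in node.members:
            owners.setdefault(int(vol), []).append(node.node_id)
    edges = set()
    by_id = {node.node_id: node for node in nodes}
    for ids in owners.values():
        for a_pos in range(len(ids)):
            for b_pos in range(a_pos + 1, len(ids)):
                a, b = ids[a_pos], ids[b_pos]
                if by_id[a].bin_id != by_id[b].bin_id:
                    edges.add((min(a, b), max(a, b)))
    return MapperGraph(nodes=list(nodes), edges=sorted(edges))


def run_mapper(x, config: MapperConfig) -> MapperGraph:
    """Full Mapper pipeline: filter, cover, partial clustering, shape graph."""
    data = x.data if isinstance(x, RoiTimeSeries) else np.asarray(x, dtype=float)
    embedding = geodesic_filter(data, config)
    bins = overlapping_bins(embedding, config)
    nodes = partial_cluster(bins, data, config)
    return shape_graph(nodes)


def high_degree_proportion(g: MapperGraph, threshold: int = 20) -> float:
    """Fraction of shape-graph nodes with degree strictly above threshold."""
    if g.n_nodes == 0:
        raise ValidityError("empty shape graph")
    return float(np.mean(g.degrees > threshold))


def condition_anova(groups: Mapping[str, Sequence[float]]
                    ) -> Tuple[float, float]:
    """One-way ANOVA F and p over condition groups (e.g. real/ARR/PR)."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValidityError("need >= 2 groups with >= 2 values each")
    within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    means = np.array([a.mean() for a in arrays])
    if within == 0.0:
        if np.ptp(means) == 0.0:
            return 0.0, 1.0
        raise DegenerateStatisticError(
            "zero within-group variance with unequal means")
    f, p = f_oneway(*arrays)
    return float(f), float(p)
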