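"""Connectivity matrices and graph metrics.

Fibers selected at a VR threshold are mapped to region pairs by their two
endpoints; a region pair with strictly more than ``min_count`` fibers
(default 3) counts as connected.  On the binarized, undirected, self-loop-free
graph we compute the average degree (AD = 2E/N), global efficiency (EG, mean
inverse shortest-path length over ordered pairs, disconnected pairs
contributing 0) and local efficiency (EL, mean over nodes of the global
efficiency of the subgraph induced on each node's neighbors).

Shortest paths run through :func:`scipy.sparse.csgraph.shortest_path`; tests
pin the metrics to a definitional brute-force oracle and to networkx.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .regions import Parcellation, StimulationMap
from .tracking import FiberRecord
from .io import labels_at

__all__ = [
    "ConnectivityMatrix",
    "count_connections",
    "binarize",
    "submatrix",
    "average_degree",
    "global_efficiency",
    "local_efficiency",
    "graph_metrics",
    "diff_metrics",
    "group_edge_prevalence",
    "MATRIX_KINDS",
]

logger = logging.getLogger(__name__)

MATRIX_KINDS = ("whole", "left", "right", "pos", "neg")

DEFAULT_MIN_FIBERS = 3  # "connected" means strictly more fibers than this


@dataclass
class ConnectivityMatrix:
    """Symmetric fiber-count matrix over an ordered node set + its adjacency."""

    node_ids: np.ndarray
    counts: np.ndarray
    adjacency: np.ndarray
    kind: str = "whole"
    vr_threshold: float | None = None
    min_count: int = DEFAULT_MIN_FIBERS

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        self.counts = np.asarray(self.counts)
        self.adjacency = np.asarray(self.adjacency)
        n = len(self.node_ids)
        if self.counts.shape != (n, n) or self.adjacency.shape != (n, n):
            raise ValueError("matrix shapes must match the node list")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("count matrix must be symmetric")
        if n and np.any(np.diagonal(self.counts)):
            raise ValueError("count matrix must have a zero diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())


def count_connections(
    fibers: list[FiberRecord] | list[np.ndarray],
    parcellation: Parcellation,
    pass_through: bool = False,
) -> tuple[np.ndarray, dict]:
    """Endpoint-based fiber count matrix over the parcellation's node set.

    Each fiber increments the cell for (region of first endpoint, region of
    last endpoint) once.  Fibers with an endpoint in background or with both
    endpoints in the same region are dropped and tallied.  With
    ``pass_through`` every unordered pair of distinct regions the fiber's
    points visit is incremented instead (sensitivity analysis; inflates hub
    connectivity).

    Returns (counts, drop_stats); drop_stats has keys ``used``,
    ``dropped_unassigned``, ``dropped_same_region``.
    """
    node_ids = parcellation.node_ids
    index = {int(r): i for i, r in enumerate(node_ids)}
    n = len(node_ids)
    counts = np.zeros((n, n), dtype=int)
    stats = {"used": 0, "dropped_unassigned": 0, "dropped_same_region": 0}
    points = [fib.points if isinstance(fib, FiberRecord) else np.asarray(fib)
              for fib in fibers]
    if pass_through:
        for pts in points:
            labels = labels_at(pts, parcellation.labels)
            regions = sorted({int(l) for l in labels if l != 0})
            if len(regions) < 2:
                key = "dropped_unassigned" if not regions else "dropped_same_region"
                stats[key] += 1
                continue
            stats["used"] += 1
            for a_i in range(len(regions)):
                for b_i in range(a_i + 1, len(regions)):
                    i, j = index[regions[a_i]], index[regions[b_i]]
                    counts[i, j] += 1
                    counts[j, i] += 1
    elif points:
        endpoints = np.concatenate([pts[[0, -1]] for pts in points])
        labels = labels_at(endpoints, parcellation.labels).reshape(-1, 2)
        for a, b in labels:
            a, b = int(a), int(b)
            if a == 0 or b == 0:
                stats["dropped_unassigned"] += 1
                continue
            if a == b:
                stats["dropped_same_region"] += 1
                continue
            i, j = index[a], index[b]
            counts[i, j] += 1
            counts[j, i] += 1
            stats["used"] += 1
    if stats["dropped_unassigned"] or stats["dropped_same_region"]:
        logger.debug("count_connections drops: %s", stats)
    return counts, stats


def binarize(counts: np.ndarray, min_count: int = DEFAULT_MIN_FIBERS) -> np.ndarray:
    """0/1 adjacency: connected iff strictly more than ``min_count`` fibers."""
    adjacency = (np.asarray(counts) > min_count).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    return adjacency


def submatrix(matrix: ConnectivityMatrix, node_subset) -> ConnectivityMatrix:
    """Induced subgraph on ``node_subset``, preserving the original node order."""
    subset = set(int(i) for i in node_subset)
    known = set(int(i) for i in matrix.node_ids)
    unknown = subset - known
    if unknown:
        raise KeyError(f"unknown node ids {sorted(unknown)}")
    keep = np.asarray([int(i) in subset for i in matrix.node_ids])
    idx = np.flatnonzero(keep)
    return ConnectivityMatrix(
        node_ids=matrix.node_ids[idx],
        counts=matrix.counts[np.ix_(idx, idx)],
        adjacency=matrix.adjacency[np.ix_(idx, idx)],
        kind=matrix.kind,
        vr_threshold=matrix.vr_threshold,
        min_count=matrix.min_count,
    )


def average_degree(adjacency: np.ndarray) -> float:
    """AD = 2E/N; 0 for the empty node set."""
    adjacency = np.asarray(adjacency)
    n = adjacency.shape[0]
    if n == 0:
        return 0.0
    return float(adjacency.sum() / n)  # sum counts each edge twice


def global_efficiency(adjacency: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Disconnected pairs contribute 0 (1/inf); graphs with fewer than two nodes
    have efficiency 0.
    """
    adjacency = np.asarray(adjacency)
    n = adjacency.shape[0]
    if n < 2:
        return 0.0
    dist = shortest_path(adjacency, method="D", directed=False, unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(adjacency: np.ndarray) -> float:
    """Mean over nodes of the neighborhood-subgraph global efficiency.

    Nodes with fewer than two neighbors contribute 0; the empty node set has
    local efficiency 0.
    """
    adjacency = np.asarray(adjacency)
    n = adjacency.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(adjacency[i])
        if len(nbrs) < 2:
            continue
        total += global_efficiency(adjacency[np.ix_(nbrs, nbrs)])
    return float(total / n)


def graph_metrics(adjacency: np.ndarray) -> dict[str, float]:
    """AD, EG, EL of one binarized adjacency (0/1 for degenerate graphs)."""
    return {
        "ad": average_degree(adjacency),
        "eg": global_efficiency(adjacency),
        "el": local_efficiency(adjacency),
    }


def diff_metrics(metrics_low: dict[str, float], metrics_high: dict[str, float]) -> dict[str, float]:
    """Metric differences between the lower and higher VR threshold.

    By edge-set nestedness ad_diff and eg_diff are non-negative; el is not
    monotone under edge addition, so el_diff may take either sign.
    """
    return {
        "ad_diff": metrics_low["ad"] - metrics_high["ad"],
        "eg_diff": metrics_low["eg"] - metrics_high["eg"],
        "el_diff": metrics_low["el"] - metrics_high["el"],
    }


def group_edge_prevalence(
    adjacencies: list[np.ndarray], min_subjects: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge count of subjects carrying that edge, plus the display mask.

    Returns (prevalence, masked) where ``masked`` zeroes edges present in
    fewer than ``min_subjects`` subjects — the rule used to declutter group
    connectivity figures.
    """
    if not adjacencies:
        raise ValueError("at least one subject adjacency required")
    stack = np.stack([np.asarray(a) > 0 for a in adjacencies])
    prevalence = stack.sum(axis=0).astype(int)
    masked = np.where(prevalence >= min_subjects, prevalence, 0)
    return prevalence, masked


def matrices_for_subject(
    counts: np.ndarray,
    parcellation: Parcellation,
    stim_map: StimulationMap | None,
    vr_threshold: float,
    min_count: int = DEFAULT_MIN_FIBERS,
) -> dict[str, ConnectivityMatrix]:
    """The five per-subject matrices (whole / left / right / pos / neg).

    ``pos``/``neg`` node sets come from the subject's stimulation map and may
    be empty; their metrics are later defined as 0 for node sets of size < 2.
    """
    whole = ConnectivityMatrix(
        node_ids=parcellation.node_ids,
        counts=counts,
        adjacency=binarize(counts, min_count),
        kind="whole",
        vr_threshold=vr_threshold,
        min_count=min_count,
    )
    out = {"whole": whole}
    subsets = {
        "left": parcellation.left_ids,
        "right": parcellation.right_ids,
        "pos": sorted(stim_map.pos_regions) if stim_map else [],
        "neg": sorted(stim_map.neg_regions) if stim_map else [],
    }
    for kind, subset in subsets.items():
        sub = submatrix(whole, subset)
        sub.kind = kind
        out[kind] = sub
    return out
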