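"""Neighbor-based background filtering.

Partially hidden (occluded/background) bacteria leave artificially small
segmentation footprints.  They are detected by local comparison: cells whose
fitted-ellipse perimeters come within 5 px (0.068 um) of each other are
adjacent, and a cell with area < 0.7x the mean area of its adjacent
neighbors is removed.  Candidate pairs are pre-screened with a KD-tree on
centroids before the exact perimeter-to-perimeter distance test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .morphometry import EllipseFit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NeighborFilterRule:
    distance_threshold_px: float = 5.0
    perimeter_samples: int = 100
    size_factor: float = 0.7


@dataclass
class AdjacencyGraph:
    """Undirected adjacency between cells, keyed by arbitrary hashable ids."""

    nodes: list
    edges: dict = field(default_factory=dict)  # frozenset({i, j}) -> distance px

    def add_edge(self, i, j, distance: float) -> None:
        if i == j:
            raise ValueError("self-edges are not allowed")
        self.edges[frozenset((i, j))] = distance

    def neighbors(self, i) -> list:
        return [next(iter(e - {i})) for e in self.edges if i in e]

    def degree(self, i) -> int:
        return sum(1 for e in self.edges if i in e)


def sample_perimeter(ellipse: EllipseFit, n: int = 100) -> np.ndarray:
    """``n`` points on the ellipse at equal parameter steps t = 2*pi*k/n.

    Points are generated in the ellipse frame and rotated/translated to image
    coordinates; returns an (n, 2) array of (x, y).
    """
    if not ellipse.fit_ok:
        raise ValueError("cannot sample the perimeter of a failed fit; exclude the cell")
    if n < 3:
        raise ValueError(f"need at least 3 perimeter samples, got {n}")
    t = 2.0 * np.pi * np.arange(n) / n
    a, b = ellipse.semi_major, ellipse.semi_minor
    phi = np.deg2rad(ellipse.orientation_deg)
    u, v = a * np.cos(t), b * np.sin(t)
    x = ellipse.center[0] + u * np.cos(phi) - v * np.sin(phi)
    y = ellipse.center[1] + u * np.sin(phi) + v * np.cos(phi)
    return np.column_stack([x, y])


def min_perimeter_distance(a: EllipseFit, b: EllipseFit, n: int = 100) -> float:
    """Minimum Euclidean distance over all n x n sampled perimeter point pairs."""
    pa = sample_perimeter(a, n)
    pb = sample_perimeter(b, n)
    return float(cdist(pa, pb).min())


def build_adjacency(
    cells: dict, rule: NeighborFilterRule = NeighborFilterRule()
) -> AdjacencyGraph:
    """Adjacency graph over ``cells`` (id -> :class:`EllipseFit`).

    A KD-tree on centers prunes pairs whose centers are farther apart than
    the sum of both semi-major axes plus the threshold (a guaranteed superset
    of true adjacencies); survivors get the exact sampled perimeter-distance
    test, and an edge is kept iff distance < threshold (strict).
    """
    ids = list(cells)
    graph = AdjacencyGraph(nodes=list(ids))
    if len(ids) < 2:
        return graph
    centers = np.array([cells[i].center for i in ids])
    semi_major = np.array([cells[i].semi_major for i in ids])
    # global prune radius: the largest pairwise bound
    r_max = 2.0 * semi_major.max() + rule.distance_threshold_px
    tree = cKDTree(centers)
    for ia, ib in sorted(tree.query_pairs(r=r_max)):
        bound = semi_major[ia] + semi_major[ib] + rule.distance_threshold_px
        if np.linalg.norm(centers[ia] - centers[ib]) > bound:
            continue
        d = min_perimeter_distance(cells[ids[ia]], cells[ids[ib]], rule.perimeter_samples)
        if d < rule.distance_threshold_px:
            graph.add_edge(ids[ia], ids[ib], d)
    return graph


def local_size_filter(
    areas: dict,
    graph: AdjacencyGraph,
    rule: NeighborFilterRule = NeighborFilterRule(),
) -> tuple[list, list]:
    """Remove locally small cells in one non-iterative pass.

    ``areas`` maps cell id -> area (px^2).  A cell is removed iff it has at
    least one neighbor in ``graph`` and its area is strictly below
    ``size_factor`` times the arithmetic mean of its neighbors' areas, with
    all decisions evaluated against the original graph (order-independent,
    no cascading).  Isolated cells are always kept.  Returns (kept, removed)
    id lists.
    """
    kept, removed = [], []
    for i in graph.nodes:
        nbrs = graph.neighbors(i)
        if nbrs and areas[i] < rule.size_factor * float(np.mean([areas[j] for j in nbrs])):
            removed.append(i)
        else:
            kept.append(i)
    if graph.nodes:
        logger.info(
            "background filter removed %d/%d cells (%.1f%%)",
            len(removed), len(graph.nodes), 100.0 * len(removed) / len(graph.nodes),
        )
    return kept, removed


def neighbor_stats(areas: dict, graph: AdjacencyGraph) -> dict:
    """Per-cell neighbor count and mean neighbor area (NaN when isolated)."""
    out = {}
    for i in graph.nodes:
        nbrs = graph.neighbors(i)
        out[i] = {
            "neighbor_count": len(nbrs),
            "mean_neighbor_area_px2": float(np.mean([areas[j] for j in nbrs])) if nbrs else np.nan,
        }
    return out
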