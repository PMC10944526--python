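"""Centerline extraction: thinning, spur pruning, endpoint-to-endpoint tracing.

A vessel mask is reduced to a one-pixel-wide, topology-preserving skeleton;
short spurious branches ("spurs", artifacts of boundary noise) are pruned;
the remaining skeleton is split at junction pixels into ordered centerline
paths, one per vessel segment, which downstream modules fit with splines.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from skimage.morphology import skeletonize as _sk_skeletonize

from .core_io import BinaryMask, logger

#: default minimum spur length (px); shorter free-end branches are noise
DEFAULT_MIN_BRANCH_LEN = 10
#: default minimum segment length (px); curvature derivatives are meaningless
#: on shorter runs
DEFAULT_MIN_SEGMENT_LEN = 30


@dataclass(frozen=True)
class CenterlinePath:
    """Ordered centerline pixels of one vessel segment, endpoint to endpoint."""

    coords: np.ndarray  # (N, 2) int array of (row, col)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=int)
        if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) < 2:
            raise ValueError("a centerline path needs >= 2 (row, col) coordinates")
        steps = np.abs(np.diff(coords, axis=0))
        if not (steps.max(axis=1) == 1).all():
            raise ValueError("consecutive path coordinates must be 8-neighbors")
        if len(np.unique(coords, axis=0)) != len(coords):
            raise ValueError("path coordinates must not repeat")
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def endpoints(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return tuple(self.coords[0]), tuple(self.coords[-1])

    def chord_lengths(self) -> np.ndarray:
        """Cumulative Euclidean chord length along the path (starts at 0)."""
        d = np.hypot(*np.diff(self.coords, axis=0).T)
        return np.concatenate([[0.0], np.cumsum(d)])


def skeletonize_mask(mask: BinaryMask) -> BinaryMask:
    """Topology-preserving morphological thinning to a 1-px-wide skeleton."""
    return BinaryMask(_sk_skeletonize(mask.grid))


def _skeleton_graph(grid: np.ndarray) -> nx.Graph:
    """8-connectivity pixel graph of a skeleton, with redundant diagonals removed.

    Thinning can leave both a diagonal link and the orthogonal two-step path
    between the same pixels (2x2 artifacts); keeping the diagonal there would
    inflate neighbor counts and fabricate junctions.  A diagonal edge is
    dropped whenever its two pixels share an orthogonal skeleton neighbor.
    """
    g = nx.Graph()
    pixels = list(map(tuple, np.argwhere(grid)))
    pixel_set = set(pixels)
    g.add_nodes_from(pixels)
    for r, c in pixels:
        for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):  # forward half-neighborhood
            q = (r + dr, c + dc)
            if q in pixel_set:
                g.add_edge((r, c), q)
    for u, v in list(g.edges):
        if abs(u[0] - v[0]) == 1 and abs(u[1] - v[1]) == 1:
            shared = ((u[0], v[1]), (v[0], u[1]))
            if any(p in pixel_set and g.has_edge(u, p) and g.has_edge(v, p) for p in shared):
                g.remove_edge(u, v)
    return g


def _junctions(g: nx.Graph) -> set:
    return {n for n in g if g.degree(n) >= 3}


def prune_spurs(skeleton: BinaryMask, min_branch_len: int = DEFAULT_MIN_BRANCH_LEN) -> BinaryMask:
    """Delete free-end branches shorter than ``min_branch_len``, to stability.

    A spur is the run of pixels from a free endpoint up to (excluding) the
    first junction; isolated open curves (no junction on the way) are never
    pruned.  Deletion can turn a junction into a plain path pixel, so the
    scan repeats until no spur remains.
    """
    grid = skeleton.grid.copy()
    while True:
        g = _skeleton_graph(grid)
        junctions = _junctions(g)
        removed_any = False
        for endpoint in [n for n in g if g.degree(n) == 1]:
            branch = [endpoint]
            prev, cur = None, endpoint
            while True:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if cur in junctions or not nbrs:
                    break
                prev, cur = cur, nbrs[0]
                if cur in junctions:
                    break
                branch.append(cur)
            if cur in junctions and len(branch) < min_branch_len:
                for p in branch:
                    grid[p] = False
                removed_any = True
        if not removed_any:
            return BinaryMask(grid)


def junction_pixels(skeleton: BinaryMask) -> np.ndarray:
    """(N, 2) coordinates of skeleton pixels with >= 3 skeleton neighbors."""
    g = _skeleton_graph(skeleton.grid)
    js = sorted(_junctions(g))
    return np.array(js, dtype=int).reshape(-1, 2)


def extract_segments(
    skeleton: BinaryMask, min_segment_len: int = DEFAULT_MIN_SEGMENT_LEN
) -> list[CenterlinePath]:
    """Split a pruned skeleton at junctions into ordered centerline paths.

    Junction pixels (>= 3 neighbors) are removed; each remaining connected
    branch is traced into an ordered path starting at its lexicographically
    smallest endpoint; paths shorter than ``min_segment_len`` pixels are
    discarded.  Closed loops (no endpoint) are opened at their smallest pixel.
    """
    g = _skeleton_graph(skeleton.grid)
    g.remove_nodes_from(_junctions(g))
    paths: list[CenterlinePath] = []
    for comp in nx.connected_components(g):
        if len(comp) < max(2, min_segment_len):
            continue
        sub = g.subgraph(comp)
        endpoints = sorted(n for n in sub if sub.degree(n) == 1)
        start = endpoints[0] if endpoints else min(comp)
        ordered = [start]
        prev: tuple | None = None
        cur = start
        while True:
            nbrs = sorted(n for n in sub.neighbors(cur) if n != prev)
            if not nbrs or nbrs[0] == start:  # end of path, or loop closed
                break
            ordered.append(nbrs[0])
            prev, cur = cur, nbrs[0]
        if len(ordered) != len(comp):
            # branched residue (should not happen on a 1-px skeleton); skip
            logger.warning("non-simple skeleton branch of %d px skipped", len(comp))
            continue
        if len(ordered) >= min_segment_len:
            paths.append(CenterlinePath(np.array(ordered)))
    paths.sort(key=lambda p: tuple(p.coords[0]))
    return paths
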