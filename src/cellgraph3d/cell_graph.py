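"""Cell interaction graph: 3D Delaunay triangulation filtered to a Gabriel graph.

Nodes are labeled cell centers (positions in physical micrometers); edges are
candidate cell-cell interactions.  The Delaunay triangulation captures the
natural spatial connectivity of the centers; the Gabriel criterion then
removes every edge {a, b} whose diameter ball contains a third center, on the
assumption that two cells only interact when no other cell sits directly
between them.  Thin stacks with exactly coplanar or collinear centers fall
back to lower-dimensional triangulations.

User edits (node add/remove/move, edge add/remove) trigger a full recompute
of the Delaunay+Gabriel edge set, after which persisted user edge edits are
re-applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import Delaunay

from .volume_io import CellCenters

__all__ = [
    "CellGraph",
    "delaunay_edges",
    "gabriel_filter",
    "gabriel_brute_force",
    "build_graph",
    "edit_graph",
    "GraphOp",
]

Edge = tuple[int, int]


def _edge_key(a: int, b: int) -> Edge:
    a, b = int(a), int(b)
    if a == b:
        raise ValueError(f"self-loop edge on node {a}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class CellGraph:
    """Graph of cell centers (physical µm) with Gabriel-filtered edges.

    ``edge_flags`` maps each edge to the subset of
    {"delaunay", "gabriel", "user_added"} that produced it; ``user_removed``
    records user-deleted edges that stay suppressed across recomputes.
    """

    nodes: dict[int, np.ndarray]  # id -> (x, y, z) micrometers
    edges: frozenset[Edge]
    edge_flags: dict[Edge, frozenset[str]] = field(default_factory=dict)
    user_removed: frozenset[Edge] = frozenset()
    user_added: frozenset[Edge] = frozenset()

    def __post_init__(self) -> None:
        for (a, b) in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a},{b}) references missing node")
            if a >= b:
                raise ValueError(f"edge ({a},{b}) not stored as sorted pair")

    def sorted_edges(self) -> list[Edge]:
        """Deterministic lexicographic edge order."""
        return sorted(self.edges)

    def edge_length(self, edge: Edge) -> float:
        a, b = edge
        return float(np.linalg.norm(self.nodes[a] - self.nodes[b]))

    def to_dict(self, spacing: Sequence[float] | None = None) -> dict:
        d = {
            "nodes": [
                {"id": i, "x": p[0], "y": p[1], "z": p[2]}
                for i, p in sorted(self.nodes.items())
            ],
            "edges": [
                {"a": a, "b": b, "flags": sorted(self.edge_flags.get((a, b), ()))}
                for a, b in self.sorted_edges()
            ],
            "user_removed": [list(e) for e in sorted(self.user_removed)],
            "coordinate_unit": "micrometer",
        }
        if spacing is not None:
            d["spacing"] = list(spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CellGraph":
        nodes = {
            int(n["id"]): np.array([n["x"], n["y"], n["z"]], dtype=float)
            for n in d["nodes"]
        }
        flags = {
            _edge_key(e["a"], e["b"]): frozenset(e.get("flags", []))
            for e in d["edges"]
        }
        return cls(
            nodes=nodes,
            edges=frozenset(flags),
            edge_flags=flags,
            user_removed=frozenset(_edge_key(a, b) for a, b in d.get("user_removed", [])),
            user_added=frozenset(e for e, f in flags.items() if "user_added" in f),
        )


def _check_coincident(ids: Sequence[int], pos: np.ndarray) -> None:
    from scipy.spatial.distance import pdist, squareform

    if len(ids) < 2:
        return
    d = squareform(pdist(pos))
    np.fill_diagonal(d, np.inf)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    if d[i, j] == 0.0:
        raise ValueError(f"coincident cell centers: ids {ids[i]} and {ids[j]}")


def delaunay_edges(positions: dict[int, np.ndarray]) -> set[Edge]:
    """Edge union of the 3D Delaunay triangulation of the given centers.

    Degenerate configurations fall back gracefully: coplanar sets are
    triangulated in their best-fit plane, collinear sets become a chain of
    consecutive points, and two points give the single edge.  Coincident
    points raise.
    """
    ids = sorted(positions)
    if len(ids) < 2:
        raise ValueError("need at least 2 nodes to build a graph")
    pts = np.array([positions[i] for i in ids], dtype=float)
    _check_coincident(ids, pts)
    if len(ids) == 2:
        return {_edge_key(ids[0], ids[1])}

    centered = pts - pts.mean(axis=0)
    # numerical rank decides the intrinsic dimension of the point set
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = s[0] if s[0] > 0 else 1.0
    rank = int(np.sum(s > 1e-9 * scale))

    if rank <= 1:
        # collinear: chain consecutive points along the principal direction
        order = np.argsort(centered @ vt[0])
        return {
            _edge_key(ids[order[k]], ids[order[k + 1]]) for k in range(len(ids) - 1)
        }

    if rank == 2 or len(ids) == 3:
        proj = centered @ vt[:2].T  # best-fit plane coordinates
        if len(ids) == 3:
            return {
                _edge_key(ids[0], ids[1]),
                _edge_key(ids[0], ids[2]),
                _edge_key(ids[1], ids[2]),
            }
        tri = Delaunay(proj)
    else:
        tri = Delaunay(pts)

    edges: set[Edge] = set()
    n_vert = tri.simplices.shape[1]
    for simplex in tri.simplices:
        for i in range(n_vert):
            for j in range(i + 1, n_vert):
                edges.add(_edge_key(ids[simplex[i]], ids[simplex[j]]))
    return edges


def gabriel_filter(
    positions: dict[int, np.ndarray], candidate_edges: Iterable[Edge]
) -> set[Edge]:
    """Keep edge {a, b} iff no third center lies strictly inside the open
    ball with diameter ab (|c − m| < |a − b| / 2, m the midpoint).

    Boundary contact (|c − m| = |ab|/2) keeps the edge: a cell *on* the disc
    is not *within* it.
    """
    ids = sorted(positions)
    idx = {i: k for k, i in enumerate(ids)}
    pts = np.array([positions[i] for i in ids], dtype=float)
    kept: set[Edge] = set()
    for a, b in candidate_edges:
        pa, pb = pts[idx[a]], pts[idx[b]]
        mid = 0.5 * (pa + pb)
        r2 = 0.25 * np.sum((pa - pb) ** 2)
        d2 = np.sum((pts - mid) ** 2, axis=1)
        d2[idx[a]] = np.inf
        d2[idx[b]] = np.inf
        if not np.any(d2 < r2):
            kept.add(_edge_key(a, b))
    return kept


def gabriel_brute_force(positions: dict[int, np.ndarray]) -> set[Edge]:
    """Independent O(n³) Gabriel oracle: test every pair of points against
    every third point with the open-ball criterion.  For points in general
    position this equals the Gabriel-filtered Delaunay edge set, since the
    Gabriel graph is a subgraph of the Delaunay triangulation."""
    ids = sorted(positions)
    out: set[Edge] = set()
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            pa, pb = positions[a], positions[b]
            mid = 0.5 * (pa + pb)
            r = 0.5 * float(np.linalg.norm(pa - pb))
            ok = True
            for c in ids:
                if c in (a, b):
                    continue
                if float(np.linalg.norm(positions[c] - mid)) < r:
                    ok = False
                    break
            if ok:
                out.add(_edge_key(a, b))
    return out


def build_graph(centers: CellCenters, spacing: Sequence[float]) -> CellGraph:
    """Delaunay + Gabriel cell graph from voxel-coordinate centers.

    Positions are converted to physical micrometers (index × spacing) before
    any geometry; deterministic for fixed input.
    """
    positions = centers.physical_positions(spacing)
    return _rebuild(positions)


def _rebuild(
    positions: dict[int, np.ndarray],
    user_added: frozenset[Edge] = frozenset(),
    user_removed: frozenset[Edge] = frozenset(),
) -> CellGraph:
    delaunay = delaunay_edges(positions)
    gabriel = gabriel_filter(positions, delaunay)
    # user additions persist while both endpoints exist; removals always win
    valid_added = frozenset(
        e for e in user_added if e[0] in positions and e[1] in positions
    )
    edges = (gabriel | valid_added) - user_removed
    flags: dict[Edge, frozenset[str]] = {}
    for e in edges:
        f = set()
        if e in delaunay:
            f.add("delaunay")
        if e in gabriel:
            f.add("gabriel")
        if e in valid_added:
            f.add("user_added")
        flags[e] = frozenset(f)
    return CellGraph(
        nodes={i: np.asarray(p, dtype=float) for i, p in positions.items()},
        edges=frozenset(edges),
        edge_flags=flags,
        user_removed=user_removed,
        user_added=valid_added,
    )


@dataclass(frozen=True)
class GraphOp:
    """One graph edit: kind in {add_node, remove_node, move_node, add_edge,
    remove_edge}; ``node``/``pos`` for node ops, ``edge`` for edge ops."""

    kind: str
    node: int | None = None
    pos: tuple[float, float, float] | None = None
    edge: Edge | None = None


def edit_graph(
    graph: CellGraph,
    ops: Sequence[GraphOp],
) -> CellGraph:
    """Apply edits and recompute.

    Node edits rebuild the full Delaunay+Gabriel edge set (exact, and cheap at
    the ~100-cell scale this targets); user edge edits are stored as flags and
    re-applied after every rebuild, so a removal persists until explicitly
    re-added and an addition persists while both endpoints exist.
    """
    positions = {i: p.copy() for i, p in graph.nodes.items()}
    user_added = set(graph.user_added)
    user_removed = set(graph.user_removed)
    for op in ops:
        if op.kind == "add_node":
            if op.node in positions:
                raise ValueError(f"node {op.node} already exists")
            positions[int(op.node)] = np.asarray(op.pos, dtype=float)
        elif op.kind == "remove_node":
            if op.node not in positions:
                raise KeyError(f"cannot remove missing node {op.node}")
            del positions[int(op.node)]
        elif op.kind == "move_node":
            if op.node not in positions:
                raise KeyError(f"cannot move missing node {op.node}")
            positions[int(op.node)] = np.asarray(op.pos, dtype=float)
        elif op.kind == "add_edge":
            e = _edge_key(*op.edge)
            if e in graph.edges and e not in user_removed:
                warnings.warn(f"edge {e} already present; add_edge is a no-op")
            else:
                user_added.add(e)
            user_removed.discard(e)
        elif op.kind == "remove_edge":
            e = _edge_key(*op.edge)
            user_removed.add(e)
            user_added.discard(e)
        else:
            raise ValueError(f"unknown graph op {op.kind!r}")
    return _rebuild(positions, frozenset(user_added), frozenset(user_removed))
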