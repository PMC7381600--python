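"""Whole-cell connectivity of the myofibrillar matrix.

A muscle cell's contractile apparatus is "unified" when every sarcomere
belongs to a single connected component under serial links plus branch
events.  This module measures the component structure and the minimal
lateral path: the shortest chain of connected sarcomeres joining two
maximally separated sarcomeres on opposite sides of the cell
cross-section, the formal counterpart of tracing only the minimal path
of connectivity across the fiber width.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from .extract import MyoGraph, SegmentationBundle

__all__ = [
    "connected_components",
    "adjacency",
    "default_endpoints",
    "minimal_lateral_path",
    "width_span_fraction",
]


def adjacency(graph: MyoGraph, edge_types: str = "all") -> dict[int, list[int]]:
    """Undirected node adjacency over serial and (optionally) event edges.

    ``edge_types`` is ``"all"`` (serial + branch events) or ``"serial"``
    (z-disk continuity only).  Event edges join every pre-event node to
    every post-event node at the event's interval.
    """
    if edge_types not in ("all", "serial"):
        raise ValueError("edge_types must be 'all' or 'serial'")
    adj: dict[int, set[int]] = {n.id: set() for n in graph.nodes}
    for u, v in graph.serial_edges:
        adj[u].add(v)
        adj[v].add(u)
    if edge_types == "all":
        for e in graph.events:
            if e.type == "ambiguous":
                continue
            k = e.interval
            members = [
                graph.by_label_interval.get((lab, k))
                for lab in (*e.parents, *e.children)
            ]
            members = [m for m in members if m is not None]
            # all segment instances meeting at a branch point are mutually
            # connected through it
            for i, u in enumerate(members):
                for v in members[i + 1 :]:
                    if u != v:
                        adj[u].add(v)
                        adj[v].add(u)
    return {u: sorted(vs) for u, vs in adj.items()}


def connected_components(graph: MyoGraph, edge_types: str = "all") -> list[set[int]]:
    """Partition of nodes under serial + event connectivity.

    Returns components sorted by decreasing size (ties by smallest
    member), so a unified matrix yields a single entry covering every
    node.
    """
    adj = adjacency(graph, edge_types)
    seen: set[int] = set()
    comps: list[set[int]] = []
    for start in sorted(adj):
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        comps.append(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def default_endpoints(graph: MyoGraph) -> tuple[int, int]:
    """The two z-interval-0 sarcomeres whose centroids are farthest apart."""
    first = [n for n in graph.nodes if n.interval == 0]
    if len(first) < 2:
        raise ValueError("need at least two sarcomeres in the first interval")
    best = None
    for i, a in enumerate(first):
        for b in first[i + 1 :]:
            d = (a.centroid[0] - b.centroid[0]) ** 2 + (a.centroid[1] - b.centroid[1]) ** 2
            if best is None or d > best[0]:
                best = (d, a.id, b.id)
    return best[1], best[2]


def minimal_lateral_path(
    graph: MyoGraph,
    source: int,
    target: int,
    edge_types: str = "all",
) -> list[int] | None:
    """Shortest node path (fewest sarcomeres) between two sarcomeres.

    Breadth-first search over serial + event edges with deterministic
    tie-breaking (neighbors visited in node-id order).  Returns the
    ordered node list, or ``None`` when the two sarcomeres are not
    connected.
    """
    if source == target:
        raise ValueError("source and target must differ")
    adj = adjacency(graph, edge_types)
    if source not in adj or target not in adj:
        raise KeyError("source/target node not in graph")
    prev: dict[int, int] = {source: source}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        if u == target:
            break
        for v in adj[u]:
            if v not in prev:
                prev[v] = u
                queue.append(v)
    if target not in prev:
        return None
    path = [target]
    while path[-1] != source:
        path.append(prev[path[-1]])
    return path[::-1]


def width_span_fraction(
    graph: MyoGraph,
    path: list[int],
    bundle: SegmentationBundle | None = None,
    cell_mask: np.ndarray | None = None,
) -> float:
    """Fraction of the cell width spanned by a path of sarcomeres.

    Node centroids are projected on the source-to-target axis; the span
    is their extent divided by the cell mask's extent along the same
    axis.  A single-node path spans 0 by definition.
    """
    if not path:
        raise ValueError("path must be nonempty")
    if len(path) == 1:
        return 0.0
    pts = np.array([graph.node(nid).centroid for nid in path])
    axis = pts[-1] - pts[0]
    norm = np.hypot(*axis)
    if norm == 0:
        return 0.0
    axis = axis / norm
    proj = pts @ axis
    span = proj.max() - proj.min()
    if cell_mask is None:
        if bundle is None:
            raise ValueError("need a bundle or cell mask for the cell extent")
        cell_mask = bundle.cell_mask
    ys, xs = np.nonzero(cell_mask)
    cell_proj = np.stack([ys, xs], axis=1) @ axis
    cell_span = cell_proj.max() - cell_proj.min()
    if cell_span == 0:
        return 0.0
    return float(min(1.0, span / cell_span))
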