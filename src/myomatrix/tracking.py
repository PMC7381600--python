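"""Myofibril tracking through the sarcomere graph.

Reproduces the manual tracking routine used on traced muscle volumes:
every sarcomere present on the first image is numbered in raster order
and followed serially through the z-disks down the length of the fiber.
Each split or merge encountered counts as one branch event, as does each
myofilament transfer or trade touching the tracked sarcomere (on either
the donor or the acceptor side — tracing cannot resolve directionality,
so the count is symmetric).  At a split the track continues with the
child whose distance from the cell membrane is closest to the track's
starting distance; ties go to the lower node id.

Only tracks whose serial structure stays within the field of view over
the entire volume are retained for frequency statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .extract import BranchEvent, MyoGraph, MyoNode, SegmentationBundle

__all__ = ["MyofibrilTrack", "seed_tracks", "track_myofibril", "fov_filter", "track_all"]


@dataclass
class MyofibrilTrack:
    """One tracked myofibril: the serial chain walked from a start node."""

    start_node: int
    start_membrane_dist_um: float
    nodes: list[int]  # one entry node per z-interval traversed
    full_path: list[int]  # includes intra-interval event hops
    events: list[tuple[int, str]]  # (event_id, type) in traversal order
    in_fov: bool
    termination: str  # "complete" | "left_volume"

    @property
    def sarcomeres_traversed(self) -> int:
        return len(self.nodes)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def branched(self) -> bool:
        return self.n_events > 0


def seed_tracks(graph: MyoGraph) -> list[int]:
    """Start nodes: every sarcomere present at the first z-disk interval.

    Nodes are numbered in deterministic raster order of their centroids
    (row, then column), which is invariant to label permutation.
    """
    starts = [
        n
        for n in graph.nodes
        if n.interval == 0 and n.start_slice == int(graph.z_disk_slices[0])
    ]
    if not starts:
        raise ValueError("no sarcomeres present in the first z-interval")
    starts.sort(key=lambda n: (n.centroid[0], n.centroid[1], n.id))
    return [n.id for n in starts]


def track_myofibril(graph: MyoGraph, start_node: int) -> MyofibrilTrack:
    """Walk one myofibril from a z-interval-0 node to the end of the volume."""
    node = graph.node(start_node)
    if node.interval != 0:
        raise ValueError("tracks must start in z-interval 0")
    d0 = node.membrane_dist_um

    def membrane_rule(children: tuple[int, ...]) -> int:
        k = graph.node(cur).interval
        cands = []
        for lab in children:
            nid = graph.by_label_interval.get((lab, k))
            if nid is not None:
                n = graph.node(nid)
                cands.append((abs(n.membrane_dist_um - d0), n.id, lab))
        if not cands:
            return children[0]
        cands.sort()
        return cands[0][2]

    cur = node.id
    nodes = [cur]
    full_path = [cur]
    events: list[tuple[int, str]] = []
    counted: set[int] = set()
    k = 0
    last_interval = graph.n_intervals - 1
    termination = "complete"

    while True:
        # intra-interval branch events on the current segment
        progressed = True
        while progressed:
            progressed = False
            cur_node = graph.node(cur)
            for e in graph.events_by_interval.get(k, []):
                if e.event_id in counted:
                    continue
                if e.slice_index < cur_node.start_slice:
                    continue
                if cur_node.label not in e.pre_labels:
                    continue
                counted.add(e.event_id)
                if e.type == "ambiguous":
                    continue
                events.append((e.event_id, e.type))
                nxt_label = e.continue_from(cur_node.label, membrane_rule)
                nid = graph.by_label_interval.get((nxt_label, k))
                if nid is not None and nid != cur:
                    cur = nid
                    full_path.append(cur)
                progressed = True
                break
        if k == last_interval:
            break
        succ = graph.serial_succ.get(cur, [])
        if not succ:
            termination = "left_volume"
            break
        cur = succ[0]
        k += 1
        nodes.append(cur)
        full_path.append(cur)

    return MyofibrilTrack(
        start_node=start_node,
        start_membrane_dist_um=d0,
        nodes=nodes,
        full_path=full_path,
        events=events,
        in_fov=(termination == "complete"),
        termination=termination,
    )


def fov_filter(
    tracks: list[MyofibrilTrack],
    bundle: SegmentationBundle | None = None,
    graph: MyoGraph | None = None,
) -> tuple[list[MyofibrilTrack], dict]:
    """Retain tracks whose serial structure stays inside the field of view.

    A track is excluded when it fails to reach the final z-interval, or —
    when a volume is supplied — when any traversed segment's footprint
    touches the lateral volume boundary.  Returns the retained tracks
    and an exclusion report.
    """
    boundary_labels: set[int] = set()
    if bundle is not None:
        vol = bundle.label_volume
        for face in (vol[:, 0, :], vol[:, -1, :], vol[:, :, 0], vol[:, :, -1]):
            boundary_labels.update(int(v) for v in np.unique(face) if v)

    retained: list[MyofibrilTrack] = []
    report = {"n_input": len(tracks), "excluded": []}
    for tr in tracks:
        if not tr.in_fov:
            report["excluded"].append((tr.start_node, tr.termination))
            continue
        if boundary_labels and graph is not None:
            labels = {graph.node(nid).label for nid in tr.full_path}
            if labels & boundary_labels:
                tr.in_fov = False
                tr.termination = "touches_lateral_boundary"
                report["excluded"].append((tr.start_node, tr.termination))
                continue
        retained.append(tr)
    report["n_retained"] = len(retained)
    return retained, report


def track_all(
    graph: MyoGraph, bundle: SegmentationBundle | None = None
) -> tuple[list[MyofibrilTrack], dict]:
    """Seed, track and FOV-filter every myofibril in one call."""
    tracks = [track_myofibril(graph, nid) for nid in seed_tracks(graph)]
    return fov_filter(tracks, bundle, graph)
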