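"""Network-graph extraction from labeled myofibrillar volumes.

The input is a segmentation of a muscle-fiber volume in which every
myofibrillar segment carries a unique positive integer label and a new
segment starts at every branch point (the convention used when tracing
sarcomeres manually through serial EM cross-sections).  Extraction turns
that volume into a graph whose nodes are sarcomere instances — one per
(segment label, z-disk interval) — and whose edges record serial
continuity through z-disks plus typed branch events: splits, merges,
myofilament transfers, and bidirectional trades.

Branch events are recognized from the label-overlap signature at the
slice where labels change:

* one label replaced by two, both persisting           -> split
* two labels replaced by one                            -> merge
* two labels replaced by two, one crossed overlap       -> transfer
* two labels replaced by two, both crossed overlaps     -> trade

Anything else is reported as ``ambiguous`` rather than dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "BranchEvent",
    "SegmentationBundle",
    "MyoNode",
    "MyoGraph",
    "overlap_links",
    "build_graph",
    "classify_events",
    "extract_graph",
    "annotate_band",
    "MIN_OVERLAP_VOX",
    "BAND_PARTITION",
]

#: Minimum shared-footprint voxel count for two labels on consecutive
#: slices to count as connected, at the reference 50 nm voxel pitch.
#: Rejects corner-touch artifacts; rescaled as (50 / pitch_nm)^2.
MIN_OVERLAP_VOX = 4

#: Sarcomere band partition by fractional position between two z-disks.
#: The z-disk-proximal zone, I-band, A-band and H-zone are symmetric
#: about the sarcomere midpoint (H-zone center).
BAND_PARTITION = (
    (0.05, "z-disk-proximal"),
    (0.20, "I-band"),
    (0.45, "A-band"),
    (0.55, "H-zone"),
    (0.80, "A-band"),
    (0.95, "I-band"),
    (1.00, "z-disk-proximal"),
)

EVENT_TYPES = ("split", "merge", "transfer", "trade")


@dataclass
class BranchEvent:
    """A typed branch event between myofibrillar segments.

    ``parents`` are the labels present on the slice before the event,
    ``children`` the labels present from ``slice_index`` on.  For trades
    the two tuples are aligned: ``children[i]`` continues ``parents[i]``.
    ``render`` carries generator-side geometry and is absent on events
    recovered from a volume.
    """

    event_id: int
    type: str
    slice_index: int
    interval: int
    phase_fraction: float
    parents: tuple[int, ...]
    children: tuple[int, ...]
    donor: int | None = None
    acceptor: int | None = None
    donor_cont: int | None = None
    acceptor_cont: int | None = None
    band: str | None = None
    render: dict | None = None

    def signature(self) -> tuple:
        """Hashable identity used to compare event multisets."""
        return (
            self.type,
            frozenset(self.parents),
            frozenset(self.children),
            self.slice_index,
        )

    @property
    def pre_labels(self) -> tuple[int, ...]:
        return self.parents

    def continue_from(self, label: int, membrane_rule=None) -> int | None:
        """Label that physically continues ``label`` through this event.

        For splits the choice between the two children is delegated to
        ``membrane_rule(children) -> label`` when given; otherwise the
        first child is returned.
        """
        if label not in self.parents:
            return None
        if self.type == "split":
            if membrane_rule is not None:
                return membrane_rule(self.children)
            return self.children[0]
        if self.type == "merge":
            return self.children[0]
        if self.type == "transfer":
            if label == self.donor:
                return self.donor_cont
            return self.acceptor_cont
        if self.type == "trade":
            return self.children[self.parents.index(label)]
        return None


@dataclass
class SegmentationBundle:
    """A labeled muscle volume plus the context needed to analyse it.

    ``label_volume`` is (n_slices, H, W) with the slice axis along the
    fiber's long axis; 0 is background.  ``z_disk_slices`` are strictly
    increasing slice indices of the z-disks; consecutive pairs delimit
    half-open sarcomere intervals [z_k, z_{k+1}).  ``cell_mask`` is a
    single (H, W) boolean mask of the cell cross-section.
    """

    label_volume: np.ndarray
    z_disk_slices: np.ndarray
    cell_mask: np.ndarray
    voxel_pitch_nm: float = 50.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.label_volume = np.asarray(self.label_volume)
        self.z_disk_slices = np.asarray(self.z_disk_slices, dtype=int)
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)

    @property
    def n_slices(self) -> int:
        return self.label_volume.shape[0]

    @property
    def n_intervals(self) -> int:
        return len(self.z_disk_slices) - 1

    @property
    def min_overlap_vox(self) -> int:
        scale = (50.0 / self.voxel_pitch_nm) ** 2
        return max(1, int(round(MIN_OVERLAP_VOX * scale)))

    def validate(self) -> None:
        z = self.z_disk_slices
        if z.ndim != 1 or len(z) < 2:
            raise ValueError("z_disk_slices must list at least two z-disks")
        if np.any(np.diff(z) <= 0):
            raise ValueError("z_disk_slices must be strictly increasing")
        if z[0] < 0 or z[-1] >= self.n_slices:
            raise ValueError(
                f"z_disk_slices must lie in [0, {self.n_slices}); got "
                f"[{z[0]}, {z[-1]}]"
            )
        if self.cell_mask.shape != self.label_volume.shape[1:]:
            raise ValueError("cell_mask shape does not match slice shape")
        outside = self.label_volume[:, ~self.cell_mask]
        if np.any(outside > 0):
            raise ValueError("labeled voxels found outside the cell mask")

    def interval_of(self, slice_index: int) -> int | None:
        """Index k of the half-open interval [z_k, z_{k+1}) holding a slice."""
        z = self.z_disk_slices
        if slice_index < z[0] or slice_index >= z[-1]:
            return None
        return int(np.searchsorted(z, slice_index, side="right") - 1)


@dataclass
class MyoNode:
    """A sarcomere instance: one segment label within one z-disk interval."""

    id: int
    label: int
    interval: int
    start_slice: int
    end_slice: int  # exclusive
    centroid: tuple[float, float]  # (y, x) in voxels
    area_vox: float
    membrane_dist_um: float
    column: int | None = None  # generator lineage id; None for extracted


@dataclass
class MyoGraph:
    """Myofibrillar network: sarcomere nodes, serial edges, branch events."""

    nodes: list[MyoNode]
    serial_edges: list[tuple[int, int]]
    events: list[BranchEvent]
    n_intervals: int
    z_disk_slices: np.ndarray
    meta: dict = field(default_factory=dict)
    candidates: list = field(default_factory=list)  # raw label transitions

    def __post_init__(self):
        self.z_disk_slices = np.asarray(self.z_disk_slices, dtype=int)
        self._index()

    def _index(self) -> None:
        self.by_label_interval: dict[tuple[int, int], int] = {
            (n.label, n.interval): n.id for n in self.nodes
        }
        self.serial_succ: dict[int, list[int]] = {}
        self.serial_pred: dict[int, list[int]] = {}
        for u, v in self.serial_edges:
            self.serial_succ.setdefault(u, []).append(v)
            self.serial_pred.setdefault(v, []).append(u)
        for d in (self.serial_succ, self.serial_pred):
            for k in d:
                d[k].sort()
        self.events_by_interval: dict[int, list[BranchEvent]] = {}
        for e in self.events:
            self.events_by_interval.setdefault(e.interval, []).append(e)
        for evs in self.events_by_interval.values():
            evs.sort(key=lambda e: (e.slice_index, e.event_id))

    def reindex(self) -> None:
        """Rebuild lookup tables after events or edges change."""
        self._index()

    def node(self, node_id: int) -> MyoNode:
        return self.nodes[node_id]

    def nodes_in_interval(self, k: int) -> list[MyoNode]:
        return [n for n in self.nodes if n.interval == k]

    def event_counts(self) -> dict[str, int]:
        out = {t: 0 for t in EVENT_TYPES + ("ambiguous",)}
        for e in self.events:
            out[e.type] = out.get(e.type, 0) + 1
        return out


# ---------------------------------------------------------------------------
# overlap scanning


def overlap_links(
    bundle: SegmentationBundle, t: int, min_overlap_vox: int | None = None
) -> list[tuple[int, int, int]]:
    """Shared-footprint links between slices ``t`` and ``t+1``.

    Returns (label_at_t, label_at_t+1, voxel_count) triples for all label
    pairs whose footprints share at least ``min_overlap_vox`` voxels,
    sorted by the pair.  Empty slices yield an empty table.
    """
    if not 0 <= t < bundle.n_slices - 1:
        raise IndexError(f"slice index {t} out of range for overlap scan")
    if min_overlap_vox is None:
        min_overlap_vox = bundle.min_overlap_vox
    a = bundle.label_volume[t].ravel()
    b = bundle.label_volume[t + 1].ravel()
    both = (a > 0) & (b > 0)
    if not both.any():
        return []
    a = a[both].astype(np.int64)
    b = b[both].astype(np.int64)
    key = a * (int(b.max()) + 1) + b
    uniq, counts = np.unique(key, return_counts=True)
    base = int(b.max()) + 1
    out = []
    for k, c in zip(uniq, counts):
        if c >= min_overlap_vox:
            out.append((int(k // base), int(k % base), int(c)))
    out.sort()
    return out


class _UnionFind:
    def __init__(self):
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        p = self.parent.setdefault(x, x)
        while p != x:
            self.parent[x] = self.parent.setdefault(p, p)
            x = self.parent[x]
            p = self.parent.setdefault(x, x)
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep the smaller (earlier) label as canonical
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


@dataclass
class _Transition:
    """A raw label transition at one slice boundary (candidate event)."""

    slice_index: int  # slice where the new labels begin
    parents: tuple[int, ...]
    children: tuple[int, ...]
    links: dict[tuple[int, int], int]


def _label_spans(volume: np.ndarray) -> dict[int, tuple[int, int]]:
    """First and last slice index of every positive label."""
    spans: dict[int, tuple[int, int]] = {}
    for t in range(volume.shape[0]):
        for lab in np.unique(volume[t]):
            if lab == 0:
                continue
            lab = int(lab)
            if lab in spans:
                spans[lab] = (spans[lab][0], t)
            else:
                spans[lab] = (t, t)
    return spans


def _scan_transitions(bundle: SegmentationBundle):
    """All overlap tables plus grouped label transitions at change boundaries."""
    vol = bundle.label_volume
    present = [set(int(v) for v in np.unique(vol[t]) if v) for t in range(bundle.n_slices)]
    tables: dict[int, list[tuple[int, int, int]]] = {}
    transitions: list[_Transition] = []
    continuations: list[tuple[int, int]] = []
    for t in range(bundle.n_slices - 1):
        ended = present[t] - present[t + 1]
        started = present[t + 1] - present[t]
        if not ended and not started:
            continue
        table = overlap_links(bundle, t)
        tables[t] = table
        changed = ended | started
        cont = {la: c for la, lb, c in table if la == lb}
        u0, c0 = np.unique(vol[t], return_counts=True)
        u1, c1 = np.unique(vol[t + 1], return_counts=True)
        area_t = dict(zip(u0.tolist(), c0.tolist()))
        area_t1 = dict(zip(u1.tolist(), c1.tolist()))
        # connected components over links touching a changed label; a link
        # involving a persisting label is kept only when substantial both
        # relative to that label's own continuation and relative to the
        # changed label's footprint (rejects slivers of footprint
        # exchanged between neighbors as an adjacent event's geometry
        # develops)
        uf = _UnionFind()
        links: dict[tuple[int, int], int] = {}
        for la, lb, c in table:
            if la not in changed and lb not in changed:
                continue
            if la not in changed or lb not in changed:
                if la not in changed:
                    ref, foot = cont.get(la), area_t1.get(lb, 0)
                else:
                    ref, foot = cont.get(lb), area_t.get(la, 0)
                if ref is not None and c < 0.25 * ref:
                    continue
                if c < 0.10 * foot:
                    continue
            uf.union(-la, lb)  # negative keys = slice-t side
            links[(la, lb)] = c
        groups: dict[int, tuple[set[int], set[int]]] = {}
        for la, lb in links:
            root = uf.find(-la)
            gp, gc = groups.setdefault(root, (set(), set()))
            gp.add(la)
            gc.add(lb)
        # ended labels with no overlap at all: terminal stumps; started with
        # none: de-novo labels.  Both are left out of event candidates.
        for _, (gp, gc) in sorted(groups.items()):
            if len(gp) == 1 and len(gc) == 1:
                la, lb = next(iter(gp)), next(iter(gc))
                if la != lb:
                    continuations.append((la, lb))
                continue
            sub = {
                (la, lb): c
                for (la, lb), c in links.items()
                if la in gp and lb in gc
            }
            transitions.append(
                _Transition(t + 1, tuple(sorted(gp)), tuple(sorted(gc)), sub)
            )
    return tables, transitions, continuations


# ---------------------------------------------------------------------------
# graph building


def build_graph(bundle: SegmentationBundle, check_connectivity: bool = True) -> MyoGraph:
    """Reconstruct the sarcomere-node graph from a labeled volume.

    One node is created per (canonical label, z-disk interval) where the
    label exists; serial edges link the same segment across z-disks.
    Raw label transitions are stored on ``graph.candidates`` for
    :func:`classify_events`.  A label change with a one-to-one overlap is
    treated as a relabeling (continuation), never as an event.
    """
    bundle.validate()
    vol = bundle.label_volume
    z = bundle.z_disk_slices
    n_int = bundle.n_intervals

    tables, transitions, continuations = _scan_transitions(bundle)
    uf = _UnionFind()
    for la, lb in continuations:
        uf.union(la, lb)
    spans = _label_spans(vol)

    def canon(lab: int) -> int:
        return uf.find(lab)

    # canonical spans
    cspans: dict[int, tuple[int, int]] = {}
    for lab, (s0, s1) in spans.items():
        c = canon(lab)
        if c in cspans:
            cspans[c] = (min(cspans[c][0], s0), max(cspans[c][1], s1))
        else:
            cspans[c] = (s0, s1)

    dist = ndimage.distance_transform_edt(bundle.cell_mask)
    um_per_vox = bundle.voxel_pitch_nm / 1000.0

    # raw -> canonical lookup per slice for footprint measurements
    canon_of = {lab: canon(lab) for lab in spans}

    nodes: list[MyoNode] = []
    by_li: dict[tuple[int, int], int] = {}
    for c, (s0, s1) in sorted(cspans.items()):
        k0 = bundle.interval_of(s0)
        k1 = bundle.interval_of(min(s1, int(z[-1]) - 1))
        if k0 is None:
            k0 = 0
        if k1 is None:
            k1 = n_int - 1
        for k in range(k0, k1 + 1):
            a, b = max(int(z[k]), s0), min(int(z[k + 1]), s1 + 1)
            if a >= b:
                continue
            mid = (a + b - 1) // 2
            sl = vol[mid]
            mask = np.zeros(sl.shape, bool)
            for lab, cc in canon_of.items():
                if cc == c:
                    mask |= sl == lab
            area = float(mask.sum())
            if area == 0:
                continue
            ys, xs = np.nonzero(mask)
            cy, cx = float(ys.mean()), float(xs.mean())
            if check_connectivity:
                comp_img, n_comp = ndimage.label(mask)
                if n_comp > 1:
                    # ignore specks below the overlap threshold (boundary
                    # noise); warn only on substantial fragmentation
                    sizes = np.bincount(comp_img.ravel())[1:]
                    if (sizes >= bundle.min_overlap_vox).sum() > 1:
                        warnings.warn(
                            f"label {c} has {n_comp} connected components "
                            f"on slice {mid}; possible segmentation error",
                            stacklevel=2,
                        )
            mdist = float(dist[int(round(cy)), int(round(cx))]) * um_per_vox
            node = MyoNode(
                id=len(nodes),
                label=c,
                interval=k,
                start_slice=a,
                end_slice=b,
                centroid=(cy, cx),
                area_vox=area,
                membrane_dist_um=mdist,
            )
            by_li[(c, k)] = node.id
            nodes.append(node)

    serial = []
    for (c, k), nid in by_li.items():
        nxt = by_li.get((c, k + 1))
        if nxt is None:
            continue
        # require the segment to actually be present on both sides of the
        # z-disk (no gap at the boundary slice)
        s0, s1 = cspans[c]
        if s0 <= int(z[k + 1]) - 1 and s1 >= int(z[k + 1]):
            serial.append((nid, nxt))
    serial.sort()

    graph = MyoGraph(
        nodes=nodes,
        serial_edges=serial,
        events=[],
        n_intervals=n_int,
        z_disk_slices=z,
        meta={
            "source": bundle.metadata.get("source", "volume"),
            "canonical_map": {int(k): int(v) for k, v in canon_of.items() if k != v},
        },
        candidates=transitions,
    )
    return graph


# ---------------------------------------------------------------------------
# event classification


def _primary_mapping(tr: _Transition) -> dict[int, int]:
    """Max-overlap child for each parent label in a transition."""
    best: dict[int, tuple[int, int]] = {}
    for (la, lb), c in tr.links.items():
        if la not in best or c > best[la][0] or (c == best[la][0] and lb < best[la][1]):
            best[la] = (c, lb)
    return {la: lb for la, (c, lb) in best.items()}


def classify_events(
    graph: MyoGraph,
    bundle: SegmentationBundle,
    persist_min_slices: int | None = None,
    trade_window_slices: int | None = None,
    taper_slices: int = 6,
) -> list[BranchEvent]:
    """Classify every candidate label transition into a typed branch event.

    The persistence rule resolves the split-vs-transfer boundary: a split
    child that merges into a pre-existing neighbor within
    ``persist_min_slices`` (default 2x the taper window) is reclassified,
    together with that merge, as a single myofilament transfer.
    Reciprocal transfers between the same pair of segments within
    ``trade_window_slices`` collapse into one trade.  Unmatched overlap
    signatures become ``ambiguous`` events — reported, never dropped.

    The resulting events are attached to ``graph.events`` (replacing any
    previous classification) and returned.
    """
    if persist_min_slices is None:
        persist_min_slices = 2 * taper_slices
    if trade_window_slices is None:
        trade_window_slices = 2 * taper_slices

    events: list[BranchEvent] = []
    for tr in sorted(graph.candidates, key=lambda tr: (tr.slice_index, tr.parents)):
        npar, nchi = len(tr.parents), len(tr.children)
        e = BranchEvent(
            event_id=len(events),
            type="ambiguous",
            slice_index=tr.slice_index,
            interval=-1,
            phase_fraction=float("nan"),
            parents=tr.parents,
            children=tr.children,
        )
        if npar == 1 and nchi == 2:
            e.type = "split"
        elif npar == 2 and nchi == 1:
            e.type = "merge"
        elif npar == 2 and nchi == 2:
            prim = _primary_mapping(tr)
            a, b = tr.parents
            pa, pb = prim.get(a), prim.get(b)
            if pa is not None and pb is not None and pa != pb:
                cross_ab = (a, pb) in tr.links
                cross_ba = (b, pa) in tr.links
                # align children with parents
                e.parents = (a, b)
                e.children = (pa, pb)
                if cross_ab and cross_ba:
                    e.type = "trade"
                elif cross_ab:
                    e.type = "transfer"
                    e.donor, e.acceptor = a, b
                    e.donor_cont, e.acceptor_cont = pa, pb
                elif cross_ba:
                    e.type = "transfer"
                    e.donor, e.acceptor = b, a
                    e.donor_cont, e.acceptor_cont = pb, pa
        events.append(e)

    events = _apply_persistence_rule(events, bundle, persist_min_slices)
    events = _pair_trades(events, trade_window_slices)

    for i, e in enumerate(events):
        e.event_id = i
        k = bundle.interval_of(e.slice_index)
        if k is not None:
            e.interval = k
            z = bundle.z_disk_slices
            e.phase_fraction = (e.slice_index - int(z[k])) / float(z[k + 1] - z[k])
            e.band = annotate_band(e)
    graph.events = [e for e in events]
    graph.reindex()
    return graph.events


def _apply_persistence_rule(events, bundle, persist_min_slices):
    """Reclassify split+prompt-remerge pairs as transfers."""
    spans = _label_spans(bundle.label_volume)
    out = list(events)
    splits = [e for e in out if e.type == "split"]
    merges = {e.event_id: e for e in out if e.type == "merge"}
    drop: set[int] = set()
    for sp in splits:
        for child in sp.children:
            s0, s1 = spans.get(child, (None, None))
            if s0 is None or s1 - sp.slice_index >= persist_min_slices:
                continue
            for me in merges.values():
                if me.event_id in drop or child not in me.parents:
                    continue
                if 0 <= me.slice_index - sp.slice_index < persist_min_slices:
                    other_parent = [p for p in me.parents if p != child][0]
                    cont = [c for c in sp.children if c != child][0]
                    tr = BranchEvent(
                        event_id=sp.event_id,
                        type="transfer",
                        slice_index=sp.slice_index,
                        interval=-1,
                        phase_fraction=float("nan"),
                        parents=(sp.parents[0], other_parent),
                        children=(cont, me.children[0]),
                        donor=sp.parents[0],
                        acceptor=other_parent,
                        donor_cont=cont,
                        acceptor_cont=me.children[0],
                    )
                    out[out.index(sp)] = tr
                    drop.add(me.event_id)
                    break
            else:
                continue
            break
    return [e for e in out if e.event_id not in drop or e.type != "merge"]


def _pair_trades(events, trade_window_slices):
    """Collapse reciprocal transfer pairs into single trade events."""
    out = []
    used: set[int] = set()
    transfers = [e for e in events if e.type == "transfer"]
    for i, e1 in enumerate(transfers):
        if e1.event_id in used:
            continue
        for e2 in transfers[i + 1 :]:
            if e2.event_id in used:
                continue
            if abs(e2.slice_index - e1.slice_index) > trade_window_slices:
                continue
            if e2.donor == e1.acceptor_cont and e2.acceptor == e1.donor_cont:
                trade = BranchEvent(
                    event_id=e1.event_id,
                    type="trade",
                    slice_index=e1.slice_index,
                    interval=-1,
                    phase_fraction=float("nan"),
                    parents=(e1.donor, e1.acceptor),
                    children=(e2.acceptor_cont, e2.donor_cont),
                )
                used.add(e1.event_id)
                used.add(e2.event_id)
                out.append(trade)
                break
        else:
            continue
    for e in events:
        if e.event_id not in used:
            out.append(e)
    out.sort(key=lambda e: (e.slice_index, e.parents))
    return out


def extract_graph(bundle: SegmentationBundle, **kwargs) -> MyoGraph:
    """Build the graph and classify its events in one call."""
    taper = int(bundle.metadata.get("taper_slices", 6))
    graph = build_graph(bundle)
    classify_events(graph, bundle, taper_slices=taper, **kwargs)
    return graph


def annotate_band(event: BranchEvent) -> str:
    """Map an event's phase fraction to its sarcomere band.

    Bands partition the z-disk-to-z-disk span symmetrically:
    z-disk-proximal [0,.05)+[.95,1), I-band [.05,.20)+[.80,.95),
    A-band [.20,.45)+[.55,.80), H-zone [.45,.55).
    """
    phase = event.phase_fraction
    if not 0 <= phase < 1:
        raise ValueError(f"phase_fraction must be in [0, 1); got {phase}")
    for hi, name in BAND_PARTITION:
        if phase < hi:
            return name
    return "z-disk-proximal"
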