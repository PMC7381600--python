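"""Synthetic myofibrillar-matrix generator.

Samples ground-truth branching networks of sarcomeres under a stochastic
per-sarcomere event model and renders them as labeled volumes that follow
the same segmentation convention as manually traced muscle volumes: one
positive integer label per myofibrillar segment, with a new label
starting at every branch point.

The model: parallel sarcomere columns sit on a jittered grid inside an
elliptical cell cross-section.  For every column and every serial
sarcomere interval an independent draw produces at most one event —

* a **split**, where a column's myofilaments separate into two daughter
  columns that partition the parent's cross-sectional territory;
* a **merge**, where two adjacent columns join into one (a split seen
  with the fiber axis reversed; static images cannot tell the two
  apart, so the pooled split/merge probability is divided by
  ``merge_fraction``);
* a **transfer**, where a fraction of one column's cross-section
  detaches and joins an adjacent column; or
* a **trade**, a reciprocal transfer between two adjacent columns at the
  same slice, recorded as a single event.

Event probabilities are per column per sarcomere interval, so
(p_split + p_transfer + p_trade) x 10 is the expected number of branch
events per ten serial sarcomeres.  Muscle-type presets carry the
measured per-10-sarcomere frequencies and transfer shares for mouse
fast-twitch, slow-twitch, cardiac and postnatal muscle and for adult
human fast-twitch fibers.

Column cross-sections are explicit pixel regions: a split cuts the
parent's region with an exact-area chord, a transfer moves a chord-cut
piece (plus a thin connecting bridge) into the acceptor, and a merge
unions the partner regions.  Footprints are therefore pairwise disjoint
and constant between events, and every event leaves its exact overlap
signature at its slice.  Setting ``min_column_radius_vox`` to 0 switches
the generator to an abstract mode without footprint geometry (used for
pure rate calibration); such networks cannot be rendered.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy import ndimage

from .extract import BranchEvent, MyoGraph, MyoNode, SegmentationBundle, annotate_band

__all__ = [
    "GeneratorConfig",
    "MyoNetwork",
    "MUSCLE_PRESETS",
    "muscle_preset",
    "simulation_config",
    "sample_network",
    "network_to_graph",
    "render_volume",
]

#: (events per sarcomere, transfer share of all events) per muscle type.
#: Frequencies are the published per-10-sarcomere branch counts / 10.
#: Transfer shares for the postnatal stages are not published; they use
#: 0.15 (the slow/cardiac range).  human_fast uses the fast-twitch share.
MUSCLE_PRESETS: dict[str, tuple[float, float]] = {
    "fast_twitch": (0.16, 0.348),
    "slow_twitch": (0.43, 0.152),
    "cardiac": (0.22, 0.138),
    "postnatal_early": (0.28, 0.15),
    "postnatal_late": (0.13, 0.15),
    "human_fast": (0.24, 0.348),
}

#: Fraction of transfer-type probability mass realised as bidirectional
#: trades.  Trades are seen but not separately quantified; one in five is
#: a conservative allocation.
TRADE_FRACTION = 0.2

#: Fraction of the donor's cross-sectional area carried by a transfer.
TRANSFER_AREA_FRACTION = 0.30

#: Per-direction area fraction exchanged by a trade; smaller than a
#: one-way transfer so the reciprocal pieces and their bridges fit side
#: by side in the corridor between the partners.
TRADE_AREA_FRACTION = 0.15

#: Smallest movable piece of cross-section, in pixels.  Below this a
#: chunk's footprint cannot reliably exceed the overlap-link threshold,
#: so such draws are suppressed instead of rendered invisibly.
MIN_CHUNK_AREA_VOX = 12.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the stochastic fiber model.

    Geometry is in voxels at ``voxel_pitch_nm`` isotropic resolution
    (50 nm default keeps desk-scale volumes while preserving topology).
    ``sarcomere_len_slices`` = 40 corresponds to a 2 um sarcomere at
    that pitch.
    """

    n_columns: int = 16
    grid_pitch_vox: float = 12.0
    column_radius_vox: float = 5.0
    n_sarcomeres: int = 24
    sarcomere_len_slices: int = 40
    p_split: float = 0.0
    p_transfer: float = 0.0
    p_trade: float = 0.0
    merge_fraction: float = 0.5
    cell_axes_vox: tuple[float, float] | None = None  # (semi_y, semi_x)
    voxel_pitch_nm: float = 50.0
    jitter_sd_vox: float = 0.5
    taper_slices: int = 6
    min_column_radius_vox: float = 2.0
    adjacency_factor: float = 1.6
    seed: int = 0

    @property
    def p_total(self) -> float:
        return self.p_split + self.p_transfer + self.p_trade

    @property
    def geometric(self) -> bool:
        """Whether footprint geometry (and rendering) is enabled."""
        return self.min_column_radius_vox > 0

    def validate(self) -> None:
        probs = (self.p_split, self.p_transfer, self.p_trade)
        if min(probs) < 0 or self.p_total > 1:
            raise ValueError("event probabilities must be >= 0 and sum to <= 1")
        if not 0 <= self.merge_fraction <= 1:
            raise ValueError("merge_fraction must lie in [0, 1]")
        if self.column_radius_vox < 2:
            raise ValueError("column_radius_vox must be >= 2")
        if self.n_columns < 1 or self.n_sarcomeres < 1:
            raise ValueError("n_columns and n_sarcomeres must be positive")
        if self.sarcomere_len_slices < 4 * self.taper_slices:
            raise ValueError(
                "sarcomere_len_slices must be >= 4 * taper_slices "
                f"({self.sarcomere_len_slices} < {4 * self.taper_slices})"
            )
        if self.cell_axes_vox is not None:
            ay, ax = self.cell_axes_vox
            need = self.n_columns * math.pi * self.column_radius_vox**2
            if need > math.pi * ay * ax:
                raise ValueError(
                    "cell ellipse too small for the configured columns: "
                    f"need area >= {need:.0f} vox^2"
                )


def muscle_preset(name: str) -> GeneratorConfig:
    """Generator configuration calibrated to a muscle type.

    The total event probability per sarcomere equals the muscle's
    measured branch frequency per 10 sarcomeres divided by 10, and the
    transfer + trade share of events equals its measured transfer share.
    Geometry fields keep the documented defaults.
    """
    if name not in MUSCLE_PRESETS:
        raise KeyError(
            f"unknown muscle preset {name!r}; valid presets: "
            + ", ".join(sorted(MUSCLE_PRESETS))
        )
    total, share = MUSCLE_PRESETS[name]
    p_tr_mass = total * share
    return GeneratorConfig(
        p_split=total - p_tr_mass,
        p_transfer=p_tr_mass * (1 - TRADE_FRACTION),
        p_trade=p_tr_mass * TRADE_FRACTION,
    )


def simulation_config(
    n_tracks: int, n_sarcomeres: int, event_rate: float, seed: int = 0
) -> GeneratorConfig:
    """Configuration for the independent per-sarcomere branching model.

    Every tracked myofibril experiences events independently at
    ``event_rate`` per sarcomere, realised as pure splits with no
    cross-column coupling and no geometric suppression, so per-track
    event counts are exactly Binomial(n_sarcomeres, event_rate).  Used
    for rate-calibration studies against printed track counts.
    """
    return GeneratorConfig(
        n_columns=n_tracks,
        n_sarcomeres=n_sarcomeres,
        p_split=event_rate,
        merge_fraction=0.0,
        jitter_sd_vox=0.0,
        min_column_radius_vox=0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ground-truth network


@dataclass
class _Segment:
    """One myofibrillar segment: a label with constant geometry.

    ``reach`` is the maximum distance from the centroid to the footprint
    boundary — the column's spatial extent, which exceeds the
    equivalent-disk radius for elongated shapes such as merge products.
    """

    label: int
    column: int
    birth: int
    death: int  # exclusive; set when the label ends
    center: np.ndarray  # (y, x), cell frame
    area: float
    mask: np.ndarray | None = None  # (H, W) footprint, volume frame
    reach: float = 0.0

    @property
    def radius(self) -> float:
        return math.sqrt(self.area / math.pi)


@dataclass
class MyoNetwork:
    """Ground-truth branching network sampled from a GeneratorConfig."""

    config: GeneratorConfig
    seed: int
    segments: list[_Segment]
    events: list[BranchEvent]
    suppressed_events: int
    cell_axes: tuple[float, float]  # (semi_y, semi_x)
    z_disk_slices: np.ndarray
    canvas_shape: tuple[int, int] | None = None
    nodes: list[MyoNode] = field(default_factory=list)
    serial_edges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_slices(self) -> int:
        return int(self.z_disk_slices[-1]) + 1

    @property
    def n_intervals(self) -> int:
        return len(self.z_disk_slices) - 1

    def validate(self) -> None:
        seg = {s.label: s for s in self.segments}
        for e in self.events:
            for lab in (*e.parents, *e.children):
                if lab not in seg:
                    raise AssertionError(f"event references unknown label {lab}")
        for u, v in self.serial_edges:
            if self.nodes[v].interval != self.nodes[u].interval + 1:
                raise AssertionError("serial edge must span consecutive intervals")
        # no dangling myofilament ends: every segment either reaches the
        # end of the volume or hands over through an event
        ends_in_event = {p for e in self.events for p in e.parents}
        for s in self.segments:
            if s.death < self.n_slices and s.label not in ends_in_event:
                raise AssertionError(f"segment {s.label} dangles at slice {s.death}")


def _grid_sites(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered lattice positions for the initial columns, cell frame."""
    pitch = config.grid_pitch_vox
    n = config.n_columns
    side = int(math.ceil(math.sqrt(n))) + 2
    ij = np.array(
        [(i, j) for i in range(-side, side + 1) for j in range(-side, side + 1)]
    )
    pts = ij * pitch
    order = np.lexsort((ij[:, 1], ij[:, 0], (pts**2).sum(axis=1)))
    pts = pts[order][:n].astype(float)
    pts += rng.uniform(-0.1 * pitch, 0.1 * pitch, size=pts.shape)
    return pts  # (n, 2) as (y, x)


def _ellipse_distance_um(p, axes, pitch_nm: float) -> float:
    """Approximate distance from an interior point to the ellipse edge."""
    ay, ax = axes
    rho = math.sqrt((p[0] / ay) ** 2 + (p[1] / ax) ** 2)
    if rho < 1e-9:
        d = min(ay, ax)
    else:
        grad = math.hypot(p[0] / ay**2, p[1] / ax**2)
        d = max(0.0, (1 - rho) * rho / grad)
    return d * pitch_nm / 1000.0


def _connected(mask: np.ndarray) -> bool:
    return mask.any() and ndimage.label(mask)[1] == 1


def _centroid(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return np.array([ys.mean(), xs.mean()])


def _mask_reach(mask: np.ndarray, centroid: np.ndarray) -> float:
    ys, xs = np.nonzero(mask)
    return float(np.sqrt((ys - centroid[0]) ** 2 + (xs - centroid[1]) ** 2).max())


def _chord_cut(mask: np.ndarray, u: np.ndarray, target: int):
    """Cut ``target`` pixels off ``mask`` on the +u side of a chord.

    Returns (piece, remainder); the chord is perpendicular to ``u`` and
    positioned so the piece has exactly ``target`` pixels (up to ties in
    the projection).
    """
    ys, xs = np.nonzero(mask)
    proj = ys * u[0] + xs * u[1]
    if target <= 0 or target >= proj.size:
        raise ValueError("chord cut target out of range")
    order = np.argsort(-proj, kind="stable")
    sel = order[:target]
    piece = np.zeros_like(mask)
    piece[ys[sel], xs[sel]] = True
    return piece, mask & ~piece


def _band_px(shape, p0, p1, halfwidth) -> np.ndarray:
    """Pixels within ``halfwidth`` of the segment p0-p1."""
    H, W = shape
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    lo = np.floor(np.minimum(p0, p1) - halfwidth - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + halfwidth + 2).astype(int)
    y0, y1 = max(0, lo[0]), min(H, hi[0])
    x0, x1 = max(0, lo[1]), min(W, hi[1])
    out = np.zeros(shape, bool)
    if y0 >= y1 or x0 >= x1:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        sel = (yy - p0[0]) ** 2 + (xx - p0[1]) ** 2 < halfwidth**2
    else:
        t = np.clip(((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / L2, 0, 1)
        sel = (yy - (p0[0] + t * d[0])) ** 2 + (xx - (p0[1] + t * d[1])) ** 2 < halfwidth**2
    out[y0:y1, x0:x1] = sel
    return out


_CUT_ANGLES = tuple(i * math.pi / 6 for i in range(6))


def _shave(mask: np.ndarray, n: int, away_from: np.ndarray) -> np.ndarray:
    """Remove ``n`` pixels from the side of ``mask`` farthest from a
    reference point, preserving connectivity; myofilament area is thereby
    conserved when a connecting bridge has been added elsewhere.
    Returns the mask unchanged when no connected shave is possible."""
    if n <= 0 or n >= mask.sum() - 1:
        return mask
    c = _centroid(mask)
    u = c - away_from
    norm = float(np.hypot(*u))
    if norm < 1e-9:
        return mask
    u = u / norm
    piece, rest = _chord_cut(mask, u, int(n))
    if _connected(rest):
        return rest
    return mask


def sample_network(config: GeneratorConfig, seed: int | None = None) -> MyoNetwork:
    """Draw a ground-truth branching network under the stochastic model.

    Events are drawn independently per column per sarcomere interval (at
    most one each) and placed at a uniform-random fractional position
    within the interval, then realised in slice order.  Partners for
    merges, transfers and trades are drawn uniformly among geometrically
    adjacent columns.  Draws that cannot be realised under the footprint
    geometry — a piece below the minimum movable size, a child below the
    minimum column radius, no adjacent partner, or a cut/bridge that
    would break a region into disconnected parts — are re-drawn as
    no-events and tallied in ``suppressed_events``.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    L = config.sarcomere_len_slices
    M = config.n_sarcomeres
    n_slices = M * L + 1
    z_disks = np.arange(0, n_slices, L)
    geometric = config.geometric

    sites = _grid_sites(config, rng)
    if config.cell_axes_vox is not None:
        axes = tuple(config.cell_axes_vox)
    else:
        pad = config.grid_pitch_vox
        axes = (
            float(np.abs(sites[:, 0]).max() + pad),
            float(np.abs(sites[:, 1]).max() + pad),
        )
    ay, ax = axes
    margin = 2.0
    H = int(math.ceil(2 * (ay + margin)))
    W = int(math.ceil(2 * (ax + margin)))
    offset = np.array([H / 2.0, W / 2.0])

    area0 = math.pi * config.column_radius_vox**2
    segments: list[_Segment] = []
    events: list[BranchEvent] = []
    suppressed = 0
    sep = 2 * config.taper_slices + 2
    min_area = math.pi * config.min_column_radius_vox**2
    # adjacency by surface gap: columns are partners when the space
    # between their footprints is at most the gap between diagonal grid
    # neighbors at nominal packing
    gap_max = max(
        2.0, config.adjacency_factor * config.grid_pitch_vox - 2 * config.column_radius_vox
    )

    next_label = 1
    next_column = 0

    def new_segment(column, birth, center, area, mask=None, reach=None) -> _Segment:
        nonlocal next_label
        center = np.asarray(center, float)
        if reach is None:
            if mask is not None:
                reach = _mask_reach(mask, center + offset)
            else:
                reach = math.sqrt(area / math.pi)
        s = _Segment(
            next_label, column, birth, n_slices, center, area, mask, reach
        )
        next_label += 1
        segments.append(s)
        return s

    # initial footprints: non-overlapping disks (ties resolved by the
    # power diagram when placement jitter makes neighbors touch)
    init_masks: list[np.ndarray | None] = [None] * len(sites)
    if geometric:
        lab_img = np.zeros((H, W), np.int32)
        score = np.full((H, W), np.inf)
        yy, xx = np.mgrid[0:H, 0:W]
        for i, p in enumerate(sites):
            cy, cx = p + offset
            sc = (yy - cy) ** 2 + (xx - cx) ** 2 - config.column_radius_vox**2
            sel = (sc < 0) & (sc < score)
            lab_img[sel] = i + 1
            score[sel] = sc[sel]
        for i in range(len(sites)):
            init_masks[i] = lab_img == i + 1

    cols: dict[int, dict] = {}
    for i, p in enumerate(sites):
        mask = init_masks[i]
        if mask is not None:
            center = _centroid(mask) - offset
            area = float(mask.sum())
        else:
            center, area = p, area0
        seg = new_segment(next_column, 0, center, area, mask)
        cols[next_column] = {"seg": seg, "guard": -sep}
        next_column += 1

    def occupied_except(*keep_labels) -> np.ndarray:
        occ = np.zeros((H, W), bool)
        for st in cols.values():
            s = st["seg"]
            if s.label not in keep_labels and s.mask is not None:
                occ |= s.mask
        return occ

    def partners_of(cid, s):
        me = cols[cid]["seg"]
        out = []
        for oid in sorted(cols):
            if oid == cid:
                continue
            other = cols[oid]["seg"]
            gap = np.hypot(*(other.center - me.center)) - me.reach - other.reach
            if gap > gap_max:
                continue
            if s < cols[oid]["guard"] + sep:
                continue
            out.append(oid)
        return out

    def record_event(etype, s, k, parents, children, **kw):
        ev = BranchEvent(
            event_id=len(events),
            type=etype,
            slice_index=int(s),
            interval=int(k),
            phase_fraction=(s - int(z_disks[k])) / float(L),
            parents=parents,
            children=children,
            **kw,
        )
        ev.band = annotate_band(ev)
        events.append(ev)
        return ev

    def try_split(seg, s):
        """Partition the column; returns (mask1, mask2, c1, c2) or None."""
        if not geometric:
            theta = rng.uniform(0, 2 * math.pi)
            u = np.array([math.sin(theta), math.cos(theta)])
            child_r = math.sqrt(seg.area / 2.0 / math.pi)
            off = u * max(seg.radius - child_r, 0.5)
            return None, None, seg.center + off, seg.center - off
        theta0 = rng.uniform(0, 2 * math.pi)
        half = int(round(seg.area / 2.0))
        for dtheta in _CUT_ANGLES:
            theta = theta0 + dtheta
            u = np.array([math.sin(theta), math.cos(theta)])
            piece, rest = _chord_cut(seg.mask, u, half)
            if _connected(piece) and _connected(rest):
                return piece, rest, None, None
        return None

    for k in range(M):
        z0, z1 = int(z_disks[k]), int(z_disks[k + 1])
        drawn = []
        for cid in sorted(cols):
            u = rng.random()
            if u < config.p_split:
                etype = "splitlike"
            elif u < config.p_split + config.p_transfer:
                etype = "transfer"
            elif u < config.p_total:
                etype = "trade"
            else:
                continue
            phase = rng.random()
            s = z0 + int(np.clip(round(phase * L), 1, L - 1))
            drawn.append((s, cid, etype))

        for s, cid, etype in sorted(drawn):
            if cid not in cols:
                suppressed += 1  # column absorbed earlier this interval
                continue
            lo = max(z0 + 1, cols[cid]["guard"] + sep)
            if s < lo:
                if lo > z1 - 1:
                    suppressed += 1
                    continue
                s = lo
            seg = cols[cid]["seg"]

            if etype == "splitlike":
                etype = "merge" if rng.random() < config.merge_fraction else "split"

            if etype == "split":
                if seg.area / 2.0 < max(min_area, MIN_CHUNK_AREA_VOX if geometric else 0):
                    suppressed += 1
                    continue
                cut = try_split(seg, s)
                if cut is None:
                    suppressed += 1
                    continue
                m1, m2, c1, c2 = cut
                if geometric:
                    c1 = _centroid(m1) - offset
                    c2 = _centroid(m2) - offset
                    a1, a2 = float(m1.sum()), float(m2.sum())
                    r1 = r2 = None
                else:
                    a1 = a2 = seg.area / 2.0
                    # a child keeps most of the parent's spatial extent:
                    # subdivision halves the area, not the territory span
                    r1 = r2 = max(math.sqrt(a1 / math.pi), 0.75 * seg.reach)
                seg.death = s
                s1 = new_segment(seg.column, s, c1, a1, m1, reach=r1)
                s2 = new_segment(next_column, s, c2, a2, m2, reach=r2)
                cols[cid]["seg"] = s1
                cols[cid]["guard"] = s
                cols[next_column] = {"seg": s2, "guard": s}
                next_column += 1
                record_event("split", s, k, (seg.label,), (s1.label, s2.label))
            elif etype == "merge":
                cands = partners_of(cid, s)
                if not cands:
                    suppressed += 1
                    continue
                oid = cands[int(rng.integers(len(cands)))]
                other = cols[oid]["seg"]
                if geometric:
                    blocked = occupied_except(seg.label, other.label)
                    bridge = (
                        _band_px((H, W), seg.center + offset, other.center + offset, 2.0)
                        & ~blocked
                        & ~(seg.mask | other.mask)
                    )
                    merged_mask = seg.mask | other.mask | bridge
                    if not _connected(merged_mask):
                        suppressed += 1
                        continue
                    merged_mask = _shave(
                        merged_mask, int(bridge.sum()), _centroid(bridge)
                        if bridge.any() else seg.center + offset,
                    )
                    tot = float(merged_mask.sum())
                    cm = _centroid(merged_mask) - offset
                    rm = None
                else:
                    merged_mask = None
                    tot = seg.area + other.area
                    cm = (seg.center * seg.area + other.center * other.area) / tot
                    # the merge product spans both parents' territories
                    rm = max(
                        float(np.hypot(*(seg.center - cm))) + seg.reach,
                        float(np.hypot(*(other.center - cm))) + other.reach,
                    )
                seg.death = s
                other.death = s
                merged = new_segment(seg.column, s, cm, tot, merged_mask, reach=rm)
                cols[cid]["seg"] = merged
                cols[cid]["guard"] = s
                del cols[oid]
                record_event("merge", s, k, (seg.label, other.label), (merged.label,))
            else:  # transfer or trade
                cands = partners_of(cid, s)
                if not cands:
                    suppressed += 1
                    continue
                oid = cands[int(rng.integers(len(cands)))]
                other = cols[oid]["seg"]
                if etype == "transfer":
                    chunk = TRANSFER_AREA_FRACTION * seg.area
                    if seg.area - chunk < min_area or (
                        geometric and chunk < MIN_CHUNK_AREA_VOX
                    ):
                        suppressed += 1
                        continue
                    if geometric:
                        u = other.center - seg.center
                        u = u / max(np.hypot(*u), 1e-9)
                        piece, rest = _chord_cut(seg.mask, u, int(round(chunk)))
                        if not (_connected(piece) and _connected(rest)):
                            suppressed += 1
                            continue
                        blocked = occupied_except(seg.label, other.label) | rest
                        bridge = (
                            _band_px(
                                (H, W),
                                _centroid(piece),
                                other.center + offset,
                                2.0,
                            )
                            & ~blocked
                            & ~(other.mask | piece)
                        )
                        acc_mask = other.mask | piece | bridge
                        if not _connected(acc_mask):
                            suppressed += 1
                            continue
                        if bridge.any():
                            acc_mask = _shave(
                                acc_mask, int(bridge.sum()), _centroid(bridge)
                            )
                        d_area, a_area = float(rest.sum()), float(acc_mask.sum())
                        d_c = _centroid(rest) - offset
                        a_c = _centroid(acc_mask) - offset
                        d_mask, a_mask = rest, acc_mask
                    else:
                        d_area, a_area = seg.area - chunk, other.area + chunk
                        d_c, a_c = seg.center, other.center
                        d_mask = a_mask = None
                    seg.death = s
                    other.death = s
                    d_reach = None if geometric else max(seg.reach, math.sqrt(d_area / math.pi))
                    a_reach = None if geometric else max(other.reach, math.sqrt(a_area / math.pi))
                    d_cont = new_segment(seg.column, s, d_c, d_area, d_mask, reach=d_reach)
                    a_cont = new_segment(other.column, s, a_c, a_area, a_mask, reach=a_reach)
                    cols[cid]["seg"] = d_cont
                    cols[cid]["guard"] = s
                    cols[oid]["seg"] = a_cont
                    cols[oid]["guard"] = s
                    record_event(
                        "transfer", s, k,
                        (seg.label, other.label), (d_cont.label, a_cont.label),
                        donor=seg.label, acceptor=other.label,
                        donor_cont=d_cont.label, acceptor_cont=a_cont.label,
                    )
                else:  # trade
                    give = TRADE_AREA_FRACTION * seg.area
                    take = TRADE_AREA_FRACTION * other.area
                    if (
                        seg.area - give < min_area
                        or other.area - take < min_area
                        or (geometric and min(give, take) < MIN_CHUNK_AREA_VOX)
                    ):
                        suppressed += 1
                        continue
                    if geometric:
                        new_masks = _trade_masks(
                            seg, other, int(round(give)), int(round(take)),
                            occupied_except(seg.label, other.label), offset, (H, W),
                        )
                        if new_masks is None:
                            suppressed += 1
                            continue
                        ma, mb = new_masks
                        a_area, b_area = float(ma.sum()), float(mb.sum())
                        a_c = _centroid(ma) - offset
                        b_c = _centroid(mb) - offset
                    else:
                        ma = mb = None
                        a_area = seg.area - give + take
                        b_area = other.area - take + give
                        a_c, b_c = seg.center, other.center
                    seg.death = s
                    other.death = s
                    s_reach = None if geometric else max(seg.reach, math.sqrt(a_area / math.pi))
                    o_reach = None if geometric else max(other.reach, math.sqrt(b_area / math.pi))
                    s_cont = new_segment(seg.column, s, a_c, a_area, ma, reach=s_reach)
                    o_cont = new_segment(other.column, s, b_c, b_area, mb, reach=o_reach)
                    cols[cid]["seg"] = s_cont
                    cols[cid]["guard"] = s
                    cols[oid]["seg"] = o_cont
                    cols[oid]["guard"] = s
                    record_event(
                        "trade", s, k,
                        (seg.label, other.label), (s_cont.label, o_cont.label),
                    )

    net = MyoNetwork(
        config=config,
        seed=seed,
        segments=segments,
        events=events,
        suppressed_events=suppressed,
        cell_axes=axes,
        z_disk_slices=z_disks,
        canvas_shape=(H, W) if geometric else None,
    )
    _build_truth_nodes(net)
    return net


def _trade_masks(seg, other, give, take, blocked, offset, shape):
    """Reciprocal exchange of chord-cut pieces between two columns.

    The two pieces are cut from laterally opposite halves of the facing
    edges so the pieces and their bridges never collide; returns the two
    new masks (for the continuations of ``seg`` and ``other``) or None
    when any part would be disconnected.
    """
    u = other.center - seg.center
    u = u / max(np.hypot(*u), 1e-9)
    perp = np.array([-u[1], u[0]])

    def side_cut(mask, towards, perp_sign, target):
        ys, xs = np.nonzero(mask)
        pperp = ys * perp[0] + xs * perp[1]
        med = np.median(pperp)
        half = mask & (
            (np.arange(shape[0])[:, None] * perp[0] + np.arange(shape[1])[None, :] * perp[1])
            * perp_sign
            >= med * perp_sign
        )
        if half.sum() <= target:
            return None
        piece, _ = _chord_cut(half, towards, target)
        return piece

    piece_a = side_cut(seg.mask, u, +1.0, give)
    piece_b = side_cut(other.mask, -u, -1.0, take)
    if piece_a is None or piece_b is None:
        return None
    if not (_connected(piece_a) and _connected(piece_b)):
        return None
    rest_a = seg.mask & ~piece_a
    rest_b = other.mask & ~piece_b
    if not (_connected(rest_a) and _connected(rest_b)):
        return None
    bridge_a = (
        _band_px(shape, _centroid(piece_a), _centroid(rest_b), 1.6)
        & ~(blocked | rest_a | piece_b | rest_b | piece_a)
    )
    bridge_b = (
        _band_px(shape, _centroid(piece_b), _centroid(rest_a), 1.6)
        & ~(blocked | rest_b | piece_a | bridge_a | rest_a | piece_b)
    )
    new_b = rest_b | piece_a | bridge_a
    new_a = rest_a | piece_b | bridge_b
    if bridge_a.any():
        new_b = _shave(new_b, int(bridge_a.sum()), _centroid(bridge_a))
    if bridge_b.any():
        new_a = _shave(new_a, int(bridge_b.sum()), _centroid(bridge_b))
    if new_a.any() and new_b.any() and (new_a & new_b).any():
        return None
    if not (_connected(new_a) and _connected(new_b)):
        return None
    return new_a, new_b


def _build_truth_nodes(net: MyoNetwork) -> None:
    """Derive (segment, interval) nodes and serial edges from segments."""
    z = net.z_disk_slices
    cfg = net.config
    nodes: list[MyoNode] = []
    by_li: dict[tuple[int, int], int] = {}
    for s in net.segments:
        k0 = max(0, int(np.searchsorted(z, s.birth, side="right")) - 1)
        last = min(s.death - 1, int(z[-1]) - 1)
        k1 = max(0, int(np.searchsorted(z, last, side="right")) - 1)
        for k in range(k0, k1 + 1):
            a, b = max(int(z[k]), s.birth), min(int(z[k + 1]), s.death)
            if a >= b:
                continue
            node = MyoNode(
                id=len(nodes),
                label=s.label,
                interval=k,
                start_slice=a,
                end_slice=b,
                centroid=(float(s.center[0]), float(s.center[1])),
                area_vox=s.area,
                membrane_dist_um=_ellipse_distance_um(
                    s.center, net.cell_axes, cfg.voxel_pitch_nm
                ),
                column=s.column,
            )
            by_li[(s.label, k)] = node.id
            nodes.append(node)
    serial = []
    for (lab, k), nid in by_li.items():
        nxt = by_li.get((lab, k + 1))
        if nxt is not None:
            serial.append((nid, nxt))
    serial.sort()
    net.nodes = nodes
    net.serial_edges = serial


def network_to_graph(net: MyoNetwork) -> MyoGraph:
    """Ground-truth network expressed as a MyoGraph (no rendering needed)."""
    return MyoGraph(
        nodes=[replace(n) for n in net.nodes],
        serial_edges=list(net.serial_edges),
        events=[replace(e) for e in net.events],
        n_intervals=net.n_intervals,
        z_disk_slices=net.z_disk_slices.copy(),
        meta={
            "source": "synthetic-truth",
            "seed": net.seed,
            "suppressed_events": net.suppressed_events,
        },
    )


# ---------------------------------------------------------------------------
# rendering


def render_volume(net: MyoNetwork, config: GeneratorConfig | None = None) -> SegmentationBundle:
    """Rasterize a network as a labeled volume bundle.

    Each segment's footprint is painted on every slice of its life span;
    a new label therefore starts exactly at each branch point, mirroring
    the manual segmentation convention.  Optional boundary noise shifts
    each footprint by an integer offset drawn per (segment, slice) with
    standard deviation ``jitter_sd_vox``.
    """
    if config is None:
        config = net.config
    if not net.config.geometric or net.canvas_shape is None:
        raise ValueError(
            "grid too small for configured geometry: this network was "
            "sampled without footprint geometry (min_column_radius_vox = 0) "
            "and cannot be rendered"
        )
    if max(s.label for s in net.segments) > np.iinfo(np.uint16).max:
        raise ValueError("too many segments for 16-bit labels")

    H, W = net.canvas_shape
    ay, ax = net.cell_axes
    cy0, cx0 = H / 2.0, W / 2.0
    n_slices = net.n_slices
    yy, xx = np.mgrid[0:H, 0:W]
    cell_mask = ((yy - cy0) / ay) ** 2 + ((xx - cx0) / ax) ** 2 <= 1.0

    rng = np.random.default_rng([int(net.seed), 7919])
    volume = np.zeros((n_slices, H, W), dtype=np.uint16)
    jitter = config.jitter_sd_vox

    for s in sorted(net.segments, key=lambda s: s.label):
        mask = s.mask
        if mask is None:
            raise ValueError(f"segment {s.label} has no footprint; cannot render")
        ys, xs = np.nonzero(mask)
        for t in range(s.birth, s.death):
            volume[t, ys, xs] = s.label

    if jitter > 0:
        # boundary noise: each slice's label boundaries are roughened by
        # randomly toggling outer-boundary pixels (erosion) and free
        # pixels adjacent to a label (dilation), at a rate scaled by the
        # requested boundary-noise standard deviation
        q = min(0.45, 0.3 * jitter)
        for t in range(n_slices):
            sl = volume[t]
            pad = np.pad(sl, 1)
            nb = np.stack(
                [pad[2:, 1:-1], pad[:-2, 1:-1], pad[1:-1, 2:], pad[1:-1, :-2]]
            )
            has_bg_neighbor = (nb == 0).any(axis=0)
            erode = (sl > 0) & has_bg_neighbor & (rng.random((H, W)) < q)
            nb_label = nb.max(axis=0)
            dilate = (
                (sl == 0)
                & (nb_label > 0)
                & cell_mask
                & (rng.random((H, W)) < q)
            )
            sl[erode] = 0
            sl[dilate] = nb_label[dilate]

    outside = volume[:, ~cell_mask]
    if np.any(outside > 0):
        raise ValueError(
            "grid too small for configured geometry: labeled voxels fall "
            "outside the cell ellipse; increase cell_axes_vox"
        )

    return SegmentationBundle(
        label_volume=volume,
        z_disk_slices=net.z_disk_slices.copy(),
        cell_mask=cell_mask,
        voxel_pitch_nm=config.voxel_pitch_nm,
        metadata={
            "source": "synthetic",
            "seed": int(net.seed),
            "taper_slices": config.taper_slices,
            "cell_axes_vox": [float(ay), float(ax)],
            "cell_center": [cy0, cx0],
            "suppressed_events": net.suppressed_events,
            "config": asdict(config),
        },
    )
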