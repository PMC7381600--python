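# Methods

## The scientific problem

Striated muscle cells have classically been described as bundles of
individual, parallel myofibrils: tube-like chains of sarcomeres running
the length of the cell.  Volume electron microscopy of labeled muscle
volumes instead shows sarcomeres branching frequently — splitting into
two structures, merging, or exchanging myofilaments with parallel
neighbors — so that the contractile apparatus forms a single connected
"myofibrillar matrix".  `myomatrix` quantifies that picture from labeled
3D segmentations: it reconstructs the sarcomere network, classifies
every branch event, measures per-volume branch-frequency statistics,
tests whole-cell connectivity, and compares muscle types.  Because the
original FIB-SEM volumes are not publicly deposited and were segmented
by hand, the package ships a synthetic generator that produces
ground-truth branching networks and rendered label volumes, so every
stage of the pipeline is validated against known truth.

## Generative model

Parallel sarcomere *columns* sit on a jittered square grid inside an
elliptical cell cross-section.  Time along the fiber axis is discretized
into sarcomere intervals delimited by z-disks (`sarcomere_len_slices`
slices each; 40 slices ≈ 2 µm at the default 50 nm isotropic voxel).
For each column and each interval an independent multinomial draw
produces at most one event:

* **split** — the column's cross-section is partitioned by a chord into
  two daughter columns of equal area;
* **merge** — the column joins an adjacent column (drawn from the pooled
  split/merge mass via `merge_fraction`, default 0.5, because a static
  image cannot distinguish a split from a merge seen in the opposite
  axial direction; merges are also what keeps the column count
  stationary while splits create new columns);
* **transfer** — 30% of the column's cross-sectional area detaches and
  joins an adjacent column;
* **trade** — a reciprocal transfer (15% of each partner's area in each
  direction) between two adjacent columns at the same slice, recorded as
  one event.

Event probabilities are per column per interval, so
`(p_split + p_transfer + p_trade) × 10` is the expected number of branch
events per ten serial sarcomeres.  Events are placed at a
uniform-random fractional position within the interval (branch points
are observed in all sarcomere bands, including near z-disks); positions
are nudged so that two events sharing a column are at least
`2·taper_slices + 2` slices apart, which keeps their overlap signatures
separable.  Partners for merges, transfers and trades are drawn
uniformly among *adjacent* columns — those whose footprint gap is at
most the diagonal-neighbor gap of the nominal packing.  Adjacency uses
each column's spatial reach (maximum centroid-to-boundary distance)
rather than the equivalent-disk radius, so elongated merge products
remain reachable by their surroundings.

### Muscle-type presets

| preset | events / sarcomere | transfer share |
|---|---|---|
| fast_twitch | 0.16 | 34.8% |
| slow_twitch | 0.43 | 15.2% |
| cardiac | 0.22 | 13.8% |
| postnatal_early | 0.28 | 15% |
| postnatal_late | 0.13 | 15% |
| human_fast | 0.24 | 34.8% |

Rates are the measured branch frequencies per 10 serial sarcomeres
divided by ten; transfer shares are the measured percentage of branches
that are myofilament transfers.  No transfer share is published for the
postnatal stages, so both use 0.15, the middle of the slow/cardiac
range; human fast-twitch muscle uses the mouse fast-twitch share.
Bidirectional trades are observed but not separately quantified; the
generator realises 20% of the transfer probability mass as trades
(`TRADE_FRACTION`).

### Geometric and abstract modes

With `min_column_radius_vox > 0` (default 2) the generator maintains an
explicit pixel footprint per segment and suppresses draws it cannot
realise: splits whose children would fall below the minimum column
area, transfers whose moving piece would be smaller than
`MIN_CHUNK_AREA_VOX` (12 px — below that a piece cannot reliably exceed
the overlap-link threshold), and cuts or bridges that would break a
region into disconnected parts.  Suppressed draws are re-drawn as
no-events and tallied in `suppressed_events`; in crowded render
geometries the realised event rate is therefore below nominal, which is
reported, never hidden.

Setting `min_column_radius_vox = 0` switches to an *abstract* mode: no
footprints, no geometric suppression, networks that cannot be rendered.
`simulation_config(n_tracks, n_sarcomeres, rate)` uses this mode with
pure splits and no cross-column coupling, which makes each tracked
myofibril's event count exactly Binomial(n_sarcomeres, rate) — the
model under which the closed-form percent-branched expression
`100·(1−(1−p)^L)` and the published track counts are compared.
Topology studies (component counts, percolation ordering, minimal
lateral paths) also run in abstract mode so that network connectivity
is not confounded by render-feasibility suppression.

### Rendering

Rendering paints each segment's constant footprint on every slice of
its life span, so a new label begins exactly at each branch point —
the same convention as manual tracing, where "the previous segment was
continued along one part and a new segment created for the other".
Footprints are pairwise disjoint and 4-connected by construction:
splits are chord partitions, transfers move a chord-cut piece together
with a thin connecting bridge into the acceptor, merges union the two
partner regions with a bridge.  Bridge pixels added for connectivity
are compensated by shaving the same number of pixels from the product's
far side, keeping the total labeled area per slice within a few percent
of the first slice (myofilament conservation).  Transitions are abrupt
at the event slice rather than morphing over a taper window: the
`taper_slices` parameter (default 6) survives as the classifier's
persistence and trade-pairing window.  Optional boundary noise
(`jitter_sd_vox`, default 0.5) roughens label boundaries by randomly
toggling boundary pixels at a rate proportional to the requested
standard deviation.

## Graph extraction and event classification

`overlap_links` tabulates shared-footprint voxel counts between
consecutive slices, thresholded at `min_overlap_vox = 4` at 50 nm voxel
pitch (scaled as `(50/pitch)²`) to reject corner-touch artifacts.  At
every slice where the label set changes, the links touching changed
labels are grouped into connected components and classified by
signature: 1→2 is a split, 2→1 a merge, 2→2 with one crossed overlap a
transfer (the donor is the label whose footprint feeds both
successors), 2→2 with both crossed overlaps a trade.  Anything else
becomes an `ambiguous` event — reported, never dropped.  A link between
a changed label and a persisting neighbor is kept only when it is
substantial (≥ 25% of the neighbor's own continuation and ≥ 10% of the
changed label's footprint); this rejects slivers of footprint exchanged
between neighbors while an adjacent event's geometry develops, without
masking true transfers.  A pure 1→1 relabeling is treated as a
continuation of the same segment, never as an event.

Two post-processing rules resolve boundaries the raw signature cannot:
a split child that merges into a pre-existing neighbor within
`persist_min_slices = 2·taper_slices` is reclassified, together with
that merge, as a single transfer; and reciprocal transfers between the
same pair within `trade_window_slices = 2·taper_slices` collapse into
one trade.  Event positions are annotated with the sarcomere band from
the phase fraction between the flanking z-disks: z-disk-proximal
[0,.05)∪[.95,1), I-band [.05,.20)∪[.80,.95), A-band [.20,.45)∪[.55,.80),
H-zone [.45,.55).  The band fractions are a documented convention — the
bands are named but not delimited numerically in the source imagery.

Nodes are (segment label, z-interval) pairs; serial edges join the same
segment across a z-disk.  Membrane distance is the 2D Euclidean
distance from the node centroid to the nearest cell-mask boundary
(distance transform), in µm.

## Tracking, field-of-view rule, metrics

Every sarcomere present on the first image is numbered in raster order
of centroids (invariant to label permutation) and walked serially
through the z-disks.  Each split or merge on the walked segment counts
as one branch; each transfer or trade touching it counts as one branch
regardless of donor/acceptor role (tracing cannot resolve transfer
directionality, so counting is symmetric).  At a split the track
continues with the child whose membrane distance is closest to the
track's starting distance; exact ties go to the lower node id.  Tracks
that fail to reach the final z-interval, or whose footprints touch the
lateral volume boundary, are excluded by the field-of-view rule.

`branch_freq_per10` is 10 × events / sarcomeres traversed over retained
tracks — events per 10 sarcomeres, which under the at-most-one-event-
per-interval model coincides with sarcomeres-containing-branches per
10.  Split-type frequency pools splits with merges; transfer-type
frequency pools transfers with trades; the two sum to the total
exactly.  `pct_branched` is the percentage of retained tracks with ≥ 1
event.  `transfer_share` uses the deduplicated volume-level event list
(each physical event once), because a transfer touches two tracks but
is one event.  Both the per-track tally (`n_events_tracked`) and the
per-volume tally (`n_events_volume`) are reported.

## Connectivity

Components are computed over serial edges plus branch events, with all
segment instances meeting at a branch point mutually connected through
it.  The minimal lateral path is an unweighted BFS (deterministic,
node-id tie-breaking) between the two first-interval sarcomeres whose
centroids are farthest apart; `width_span_fraction` projects the path's
centroids on the source→target axis and divides by the cell mask's
extent along that axis.  A `serial`-only edge mode is available for
asking whether connectivity requires branch edges at all.

## Group statistics

Muscle types are compared by one-way ANOVA with Tukey's HSD post-hoc
test at family-wise α = 0.05, the muscle volume as the unit of analysis
(means ± SE over volumes).  The F statistic comes from
`scipy.stats.f_oneway`; Tukey adjusted p-values are the studentized-
range tail probability of `|Δmean| / sqrt(MSW/2·(1/nᵢ+1/nⱼ))` with the
Tukey–Kramer allowance for unequal group sizes.  Degenerate inputs
(fewer than two groups, singleton groups, zero pooled within-variance)
raise explicit errors rather than propagating NaN.

## Problem sizes used in the validation suite

Round-trip and invariance checks render 9-column × 4-sarcomere volumes
(~161 slices of ~66×58 voxels) across all six presets; rate-calibration
studies track 60–193 myofibrils over 13–18 sarcomeres for 20–60
simulations per condition; percolation uses the 16-column × 24-sarcomere
default fiber.  These sizes were chosen so the whole suite exercises
every code path at desk scale while each study retains enough events
for its statistical tolerance.

## Known limitations

* The generator's independence assumptions (at most one event per
  column per interval, no clustering of events along a myofibril, no
  spatial rate gradients) are conveniences, not measurements; passing
  tests show the *pipeline* is correct under the stated model, not that
  real muscle follows it.
* Geometric mode suppresses infeasible draws, so realised event rates
  in rendered volumes sit below nominal in crowded configurations; the
  suppressed tally quantifies this.
* Rendered transitions are abrupt at the event slice; gradual taper
  morphology of real branch points is not emulated.
* Transfer donor/acceptor roles are assigned from slice-order geometry;
  this is a convention, not biology — static volumes cannot show which
  sarcomere donates.
* Vernier z-disk-sheet displacements, grayscale EM appearance,
  mitochondria/SR/t-tubule context, and any temporal dynamics are out
  of scope.
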