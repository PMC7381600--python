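# myomatrix

Sarcomere-branching and myofibrillar-matrix analysis for labeled 3D
muscle volumes.

Striated muscle is textbook-drawn as many individual, parallel
myofibrils — end-to-end chains of sarcomeres.  High-resolution volume
electron microscopy instead shows sarcomeres branching frequently:
splitting into two structures, merging, and transferring myofilaments
to parallel neighbors, so that the whole contractile apparatus forms
one connected **myofibrillar matrix**.  `myomatrix` turns a labeled
segmentation of a muscle fiber (one integer label per myofibrillar
segment, a new label at every branch point) into quantitative
statements about that matrix:

* **graph extraction** — sarcomere nodes between consecutive z-disks,
  serial connectivity, and typed branch events (split, merge,
  myofilament transfer, bidirectional trade) classified from
  slice-to-slice label-overlap signatures;
* **tracking** — every myofibril present on the first image is followed
  serially down the fiber, counting the branches it encounters, with
  the field-of-view rule excluding structures that leave the volume;
* **metrics** — branches per 10 serial sarcomeres, the percentage of
  myofibrils containing ≥ 1 branch, and the transfer share of all
  branch events, per volume;
* **connectivity** — connected components of the matrix and the minimal
  lateral path of sarcomeres spanning the cell width;
* **statistics** — one-way ANOVA with Tukey's HSD across muscle types,
  the muscle volume as the unit of analysis;
* **synthetic data** — a stochastic generator of ground-truth branching
  networks with muscle-type presets (mouse fast-twitch, slow-twitch,
  cardiac, early/late postnatal; adult human fast-twitch), rendered as
  label volumes, so the full pipeline is validated against known truth.

The central quantity is the per-sarcomere branch probability *p*: the
generator draws at most one event per sarcomere column per serial
interval, so a myofibril of *L* sarcomeres branches at least once with
probability 1 − (1 − p)^L, and the expected branch frequency is 10·p
per 10 sarcomeres.  Measured rates span p = 0.13 (late postnatal) to
p = 0.43 (slow-twitch).

## Worked example

Simulate a small slow-twitch fiber, recover its network, track its
myofibrils, and summarize:

```sh
myomatrix simulate --preset slow_twitch --seed 3 --n-columns 9 \
    --n-sarcomeres 4 --out-volume v.tif --out-truth truth.json
myomatrix extract --volume v.tif --meta v.meta.json \
    --out-graph g.json --out-events events.csv
myomatrix track --graph g.json --volume v.tif --meta v.meta.json \
    --out-tracks tracks.jsonl
myomatrix metrics --tracks tracks.jsonl --events events.csv \
    --group slow --volume-id vol1 --out m1.csv
```

which prints

```
simulated slow_twitch: 9 columns x 4 sarcomeres, 12 events (4 suppressed), seed 3
extracted 59 sarcomere nodes, 29 serial edges, events: split=8, merge=3, transfer=1
9/9 tracks retained (0 excluded by the field-of-view rule)
vol1: 4.17 branches/10 sarcomeres, 100.0% of myofibrils branched
```

Nine parallel sarcomere columns were followed through four serial
sarcomeres each; the twelve ground-truth branch events rendered into
the volume were recovered and classified from label overlaps, and the
tracked branch frequency (4.17 per 10 sarcomeres) sits at the
slow-twitch generative rate (4.3 per 10) for this small sample.  Every
myofibril encountered at least one branch — at slow-twitch rates a
four-sarcomere stretch is branched with probability
1 − 0.57⁴ ≈ 0.89 per track.  The same objects are available in Python
via `myomatrix.sample_network`, `render_volume`, `extract_graph`,
`track_all`, `volume_summary`, `connected_components` and
`group_compare`.

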