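"""Graph extraction: overlap links, node/edge recovery, event typing."""

import dataclasses

import numpy as np
import pytest

import myomatrix as mm
from myomatrix.extract import annotate_band, BranchEvent

from conftest import render_pair


def brute_force_overlaps(vol, t, min_overlap):
    """Exhaustive voxel-pair enumeration oracle for overlap_links."""
    counts = {}
    a, b = vol[t], vol[t + 1]
    for y in range(a.shape[0]):
        for x in range(a.shape[1]):
            la, lb = int(a[y, x]), int(b[y, x])
            if la and lb:
                counts[(la, lb)] = counts.get((la, lb), 0) + 1
    return sorted(
        (la, lb, c) for (la, lb), c in counts.items() if c >= min_overlap
    )


def make_bundle(vol, z=None):
    vol = np.asarray(vol, np.uint16)
    mask = np.ones(vol.shape[1:], bool)
    if z is None:
        z = [0, vol.shape[0] - 1]
    return mm.SegmentationBundle(vol, np.asarray(z), mask)


class TestOverlapLinks:
    def test_identity_slices_link_each_label_to_itself(self):
        sl = np.zeros((8, 8), np.uint16)
        sl[1:4, 1:4] = 3
        sl[4:7, 4:7] = 5
        bundle = make_bundle([sl, sl])
        assert mm.overlap_links(bundle, 0) == [(3, 3, 9), (5, 5, 9)]

    def test_label_covered_by_two_successors(self):
        a = np.zeros((6, 8), np.uint16)
        a[1:5, 1:7] = 2
        b = np.zeros((6, 8), np.uint16)
        b[1:5, 1:4] = 7
        b[1:5, 4:7] = 9
        bundle = make_bundle([a, b])
        assert mm.overlap_links(bundle, 0) == [(2, 7, 12), (2, 9, 12)]

    def test_empty_slice_gives_empty_table(self):
        bundle = make_bundle(np.zeros((2, 5, 5)))
        assert mm.overlap_links(bundle, 0) == []

    def test_out_of_range_slice_rejected(self):
        bundle = make_bundle(np.zeros((2, 5, 5)))
        with pytest.raises(IndexError):
            mm.overlap_links(bundle, 1)

    def test_matches_brute_force_enumeration_on_rendered_volume(self):
        net, bundle = render_pair("cardiac", 6)
        for t in (0, 41, 83, bundle.n_slices - 2):
            expected = brute_force_overlaps(
                bundle.label_volume, t, bundle.min_overlap_vox
            )
            assert mm.overlap_links(bundle, t) == expected


class TestBuildGraph:
    def test_unbranched_counts(self, unbranched_bundle):
        net, bundle = unbranched_bundle
        graph = mm.extract_graph(bundle)
        assert len(graph.nodes) == 6 * 3
        assert len(graph.serial_edges) == 6 * 2
        assert graph.events == []

    def test_single_split_graph_matches_truth(self, split_volume):
        """The extracted graph is label-for-label identical to the
        generator's ground truth."""
        net, bundle = split_volume
        truth = mm.network_to_graph(net)
        graph = mm.extract_graph(bundle)
        assert {(n.label, n.interval) for n in graph.nodes} == {
            (n.label, n.interval) for n in truth.nodes
        }
        def edge_labels(g):
            return {
                ((g.node(u).label, g.node(u).interval),
                 (g.node(v).label, g.node(v).interval))
                for u, v in g.serial_edges
            }
        assert edge_labels(graph) == edge_labels(truth)
        assert sorted(e.signature() for e in graph.events) == sorted(
            e.signature() for e in truth.events
        )

    def test_pure_relabeling_is_continuation_not_event(self):
        """A label change with one-to-one full overlap is a relabeling of
        the same segment."""
        sl = np.zeros((10, 10), np.uint16)
        sl[2:8, 2:8] = 4
        sl2 = sl.copy()
        sl2[sl2 == 4] = 9
        vol = np.stack([sl, sl, sl2, sl2])
        bundle = make_bundle(vol, z=[0, 2, 3])
        graph = mm.extract_graph(bundle)
        assert graph.events == []
        assert len(graph.nodes) == 2  # one segment across two intervals
        assert len(graph.serial_edges) == 1

    def test_relabeling_invariance(self):
        """Permuting label integers changes no extracted topology."""
        net, bundle = render_pair("slow_twitch", 8)
        graph = mm.extract_graph(bundle)
        labels = sorted(set(np.unique(bundle.label_volume)) - {0})
        rng = np.random.default_rng(0)
        perm = dict(zip(labels, rng.permutation(labels)))
        lut = np.zeros(max(labels) + 1, np.uint16)
        for a, b in perm.items():
            lut[a] = b
        vol2 = lut[bundle.label_volume]
        bundle2 = mm.SegmentationBundle(
            vol2, bundle.z_disk_slices, bundle.cell_mask,
            bundle.voxel_pitch_nm, dict(bundle.metadata),
        )
        graph2 = mm.extract_graph(bundle2)

        def canon(sigs, mapping=None):
            mapping = mapping or {}
            return sorted(
                (t, tuple(sorted(int(mapping.get(p, p)) for p in ps)),
                 tuple(sorted(int(mapping.get(c, c)) for c in cs)), s)
                for t, ps, cs, s in sigs
            )

        assert canon((e.signature() for e in graph.events), perm) == canon(
            e.signature() for e in graph2.events
        )
        assert {(perm[n.label], n.interval) for n in graph.nodes} == {
            (n.label, n.interval) for n in graph2.nodes
        }


class TestClassifyEvents:
    def test_transfer_has_correct_roles_and_slice(self):
        for seed in range(40):
            net, bundle = render_pair("fast_twitch", seed)
            truth_tr = [e for e in net.events if e.type == "transfer"]
            if not truth_tr:
                continue
            graph = mm.extract_graph(bundle)
            got = [e for e in graph.events if e.type == "transfer"]
            assert {(e.donor, e.acceptor, e.slice_index) for e in got} >= {
                (e.donor, e.acceptor, e.slice_index) for e in truth_tr
            }
            return
        pytest.skip("no transfer drawn")

    def test_trade_is_one_event_not_two_transfers(self):
        for seed in range(60):
            net, bundle = render_pair("fast_twitch", seed)
            truth_trades = [e for e in net.events if e.type == "trade"]
            if not truth_trades:
                continue
            graph = mm.extract_graph(bundle)
            got = [e for e in graph.events if e.type == "trade"]
            assert len(got) == len(truth_trades)
            assert {e.signature() for e in got} == {
                e.signature() for e in truth_trades
            }
            return
        pytest.fail("no trade drawn in 60 seeds")

    def test_mirror_invariance_swaps_splits_and_merges(self):
        """Reversing the slice axis swaps split and merge counts and
        leaves transfer + trade counts unchanged."""
        for seed in (1, 5, 7):
            net, bundle = render_pair("cardiac", seed)
            graph = mm.extract_graph(bundle)
            n = bundle.n_slices
            rbundle = mm.SegmentationBundle(
                bundle.label_volume[::-1].copy(),
                (n - 1 - bundle.z_disk_slices)[::-1].copy(),
                bundle.cell_mask, bundle.voxel_pitch_nm, dict(bundle.metadata),
            )
            rgraph = mm.extract_graph(rbundle)
            c, rc = graph.event_counts(), rgraph.event_counts()
            assert c["split"] == rc["merge"] and c["merge"] == rc["split"]
            assert c["transfer"] + c["trade"] == rc["transfer"] + rc["trade"]

    def test_ambiguous_signature_reported_not_dropped(self):
        """A 2->2 transition whose overlaps do not match any branch
        pattern (both old labels flowing mainly into the same new one)
        is reported as 'ambiguous', never silently dropped."""
        a = np.zeros((14, 12), np.uint16)
        a[1:6, 2:10] = 1
        a[6:12, 2:10] = 2
        b = np.zeros((14, 12), np.uint16)
        b[1:10, 2:10] = 3   # main successor of both 1 and 2
        b[10:13, 2:10] = 4  # minor successor of 2 only
        vol = np.stack([a, a, b, b])
        bundle = make_bundle(vol, z=[0, 3])
        graph = mm.extract_graph(bundle)
        assert [e.type for e in graph.events] == ["ambiguous"]
        assert set(graph.events[0].parents) == {1, 2}
        assert set(graph.events[0].children) == {3, 4}


class TestBandAnnotation:
    @pytest.mark.parametrize("phase,band", [
        (0.02, "z-disk-proximal"),
        (0.10, "I-band"),
        (0.30, "A-band"),
        (0.50, "H-zone"),
        (0.70, "A-band"),
        (0.90, "I-band"),
        (0.97, "z-disk-proximal"),
    ])
    def test_partition(self, phase, band):
        e = BranchEvent(0, "split", 0, 0, phase, (1,), (2, 3))
        assert annotate_band(e) == band

    def test_invalid_phase_rejected(self):
        e = BranchEvent(0, "split", 0, 0, 1.2, (1,), (2, 3))
        with pytest.raises(ValueError):
            annotate_band(e)

    def test_all_bands_observed_under_uniform_phases(self):
        """Uniform-random event positions populate all four bands, as
        branch points occur in all sarcomere regions."""
        bands = set()
        for seed in range(25):
            cfg = dataclasses.replace(
                mm.muscle_preset("slow_twitch"),
                n_columns=9, n_sarcomeres=4, min_column_radius_vox=0.0, seed=seed,
            )
            net = mm.sample_network(cfg, seed)
            bands |= {e.band for e in net.events}
        assert bands == {"z-disk-proximal", "I-band", "A-band", "H-zone"}


class TestBundleValidation:
    def test_label_outside_mask_rejected(self):
        vol = np.ones((2, 4, 4), np.uint16)
        mask = np.zeros((4, 4), bool)
        b = mm.SegmentationBundle(vol, np.array([0, 1]), mask)
        with pytest.raises(ValueError, match="outside the cell mask"):
            b.validate()

    def test_nonmonotone_zdisks_rejected(self):
        vol = np.zeros((4, 4, 4), np.uint16)
        b = mm.SegmentationBundle(vol, np.array([0, 2, 2]), np.ones((4, 4), bool))
        with pytest.raises(ValueError, match="strictly increasing"):
            b.validate()
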