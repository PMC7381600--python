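"""Generator: presets, sampling statistics, rendering invariants."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

import myomatrix as mm
from myomatrix.synthetic import MUSCLE_PRESETS

from conftest import PRESET_CYCLE, render_pair


class TestPresets:
    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(KeyError, match="fast_twitch"):
            mm.muscle_preset("gastrocnemius")

    @pytest.mark.parametrize("name,total,share", [
        ("slow_twitch", 0.43, 0.152),
        ("fast_twitch", 0.16, 0.348),
        ("cardiac", 0.22, 0.138),
        ("human_fast", 0.24, 0.348),
        ("postnatal_early", 0.28, 0.15),
        ("postnatal_late", 0.13, 0.15),
    ])
    def test_preset_rates_and_transfer_share(self, name, total, share):
        """Total event probability x10 matches the muscle's branch
        frequency per 10 sarcomeres; transfer+trade share matches the
        measured percentage of transfers among branches."""
        cfg = mm.muscle_preset(name)
        assert cfg.p_total == pytest.approx(total)
        assert (cfg.p_transfer + cfg.p_trade) / cfg.p_total == pytest.approx(share)
        cfg.validate()

    def test_all_presets_enumerated(self):
        assert set(MUSCLE_PRESETS) == {
            "fast_twitch", "slow_twitch", "cardiac",
            "postnatal_early", "postnatal_late", "human_fast",
        }

    def test_config_invariants_rejected(self):
        with pytest.raises(ValueError):
            mm.GeneratorConfig(p_split=0.7, p_transfer=0.4).validate()
        with pytest.raises(ValueError):
            mm.GeneratorConfig(column_radius_vox=1.0).validate()
        with pytest.raises(ValueError):
            mm.GeneratorConfig(sarcomere_len_slices=10, taper_slices=6).validate()
        with pytest.raises(ValueError):
            mm.GeneratorConfig(n_columns=100, cell_axes_vox=(10, 10)).validate()


class TestSampling:
    def test_zero_rates_give_disjoint_unbranched_chains(self):
        cfg = mm.GeneratorConfig(n_columns=7, n_sarcomeres=5, seed=1)
        net = mm.sample_network(cfg, 1)
        assert len(net.events) == 0
        assert len(net.segments) == 7
        graph = mm.network_to_graph(net)
        assert len(graph.nodes) == 7 * 5
        assert len(graph.serial_edges) == 7 * 4
        assert len(mm.connected_components(graph)) == 7

    def test_mean_tracked_event_count_matches_binomial(self):
        """100 tracked myofibrils x 20 intervals at p_split=0.1: each
        track's event count is Bernoulli per interval, so the mean total
        over 200 seeds sits within 3 binomial standard errors of
        n*M*p = 200."""
        n, M, p, seeds = 100, 20, 0.1, 200
        counts = []
        for s in range(seeds):
            cfg = mm.simulation_config(n, M, p, seed=s)
            net = mm.sample_network(cfg, s)
            retained, _ = mm.track_all(mm.network_to_graph(net))
            counts.append(sum(t.n_events for t in retained))
        mean = np.mean(counts)
        se = np.sqrt(n * M * p * (1 - p) / seeds)
        assert abs(mean - n * M * p) < 3 * se

    def test_slow_twitch_ground_truth_rate(self):
        """Measured ground-truth event rate under the slow-twitch rates
        is ~4.3 per 10 sarcomere intervals of exposure."""
        tot = expo = 0
        for s in range(30):
            cfg = dataclasses.replace(
                mm.muscle_preset("slow_twitch"),
                n_columns=30, n_sarcomeres=13, min_column_radius_vox=0.0, seed=s,
            )
            net = mm.sample_network(cfg, s)
            tot += len(net.events) + net.suppressed_events
            z = net.z_disk_slices
            expo += sum(1 for nd in net.nodes if nd.start_slice == int(z[nd.interval]))
        assert 10 * tot / expo == pytest.approx(4.3, abs=0.15)

    def test_reproducible_network_and_volume(self):
        net1, b1 = render_pair("cardiac", 11)
        net2, b2 = render_pair("cardiac", 11)
        assert [e.signature() for e in net1.events] == [e.signature() for e in net2.events]
        assert np.array_equal(b1.label_volume, b2.label_volume)

    def test_network_invariants_hold(self):
        for seed in range(5):
            net, _ = render_pair(PRESET_CYCLE[seed], seed)
            net.validate()

    def test_unrenderable_abstract_network(self):
        cfg = mm.simulation_config(5, 3, 0.2, seed=0)
        net = mm.sample_network(cfg, 0)
        with pytest.raises(ValueError, match="cannot be rendered"):
            mm.render_volume(net, cfg)


class TestRendering:
    def test_unbranched_render_identity_overlaps(self, unbranched_bundle):
        """Every label appears on every slice and consecutive-slice
        overlap maps are one-to-one."""
        net, bundle = unbranched_bundle
        vol = bundle.label_volume
        labels = set(np.unique(vol[0])) - {0}
        assert len(labels) == 6
        for t in range(bundle.n_slices):
            assert set(np.unique(vol[t])) - {0} == labels
        links = mm.overlap_links(bundle, 0)
        assert [(a, b) for a, b, _ in links] == sorted((l, l) for l in labels)

    def test_footprints_disjoint_and_connected(self):
        net, bundle = render_pair("slow_twitch", 4)
        vol = bundle.label_volume
        for t in range(0, bundle.n_slices, 17):
            sl = vol[t]
            total = (sl > 0).sum()
            per_label = sum((sl == l).sum() for l in np.unique(sl) if l)
            assert per_label == total  # one label per voxel by construction
            for l in np.unique(sl):
                if l:
                    assert ndimage.label(sl == l)[1] == 1

    def test_split_signature_at_event_slice(self, split_volume):
        """At a split's slice, one label ends and two begin, both
        overlapping the ended label's footprint."""
        net, bundle = split_volume
        ev = next(e for e in net.events if e.type == "split")
        s = ev.slice_index
        links = dict(
            ((a, b), c) for a, b, c in mm.overlap_links(bundle, s - 1)
        )
        parent = ev.parents[0]
        for child in ev.children:
            assert links.get((parent, child), 0) >= bundle.min_overlap_vox

    def test_per_slice_area_conservation(self):
        """Total labeled area per slice stays within 10% of slice 0."""
        for seed in (2, 9):
            net, bundle = render_pair("slow_twitch", seed)
            areas = (bundle.label_volume > 0).sum(axis=(1, 2))
            assert np.all(np.abs(areas - areas[0]) <= 0.10 * areas[0])

    def test_truth_and_volume_mutually_consistent(self):
        """Every recorded event's label adjacency at its slice matches
        its type signature (brute-force overlap enumeration)."""
        net, bundle = render_pair("cardiac", 15)
        for ev in net.events:
            links = mm.overlap_links(bundle, ev.slice_index - 1)
            pairs = {(a, b) for a, b, _ in links}
            if ev.type == "split":
                (p,) = ev.parents
                assert all((p, c) in pairs for c in ev.children)
            elif ev.type == "merge":
                (c,) = ev.children
                assert all((p, c) in pairs for p in ev.parents)
            elif ev.type == "transfer":
                assert (ev.donor, ev.donor_cont) in pairs
                assert (ev.donor, ev.acceptor_cont) in pairs
                assert (ev.acceptor, ev.acceptor_cont) in pairs
            elif ev.type == "trade":
                a, b = ev.parents
                ca, cb = ev.children
                assert {(a, ca), (a, cb), (b, ca), (b, cb)} <= pairs

    def test_metadata_carries_seed_and_config(self):
        net, bundle = render_pair("fast_twitch", 3)
        assert bundle.metadata["seed"] == 3
        assert bundle.metadata["config"]["n_columns"] == 9
        assert bundle.metadata["suppressed_events"] == net.suppressed_events
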