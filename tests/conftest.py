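import dataclasses

import pytest

import myomatrix as mm

PRESET_CYCLE = [
    "fast_twitch",
    "slow_twitch",
    "cardiac",
    "postnatal_early",
    "postnatal_late",
    "human_fast",
]


def small_render_config(preset: str, seed: int, **overrides) -> mm.GeneratorConfig:
    """Desk-scale render configuration: default geometry, small size."""
    base = dict(n_columns=9, n_sarcomeres=4, jitter_sd_vox=0.0, seed=seed)
    base.update(overrides)
    return dataclasses.replace(mm.muscle_preset(preset), **base)


def render_pair(preset: str, seed: int, **overrides):
    """(network, rendered bundle) for a small noiseless volume."""
    cfg = small_render_config(preset, seed, **overrides)
    net = mm.sample_network(cfg, seed)
    return net, mm.render_volume(net, cfg)


@pytest.fixture(scope="session")
def split_volume():
    """A small volume guaranteed to contain at least one split."""
    for seed in range(20):
        net, bundle = render_pair("fast_twitch", seed)
        if any(e.type == "split" for e in net.events):
            return net, bundle
    raise RuntimeError("no split drawn in 20 seeds")


@pytest.fixture(scope="session")
def unbranched_bundle():
    cfg = dataclasses.replace(
        mm.GeneratorConfig(), n_columns=6, n_sarcomeres=3, jitter_sd_vox=0.0, seed=0
    )
    net = mm.sample_network(cfg, 0)
    return net, mm.render_volume(net, cfg)
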