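import dataclasses

import pytest

from kinegait.pipeline import RunConfig, run_trial
from kinegait.segmentation import SegmentationConfig
from kinegait.synthetic_gait import preset, simulate_walk

#: analysis window wide enough to keep every stride of a long synthetic walk
WIDE_VGAP = SegmentationConfig(vgap_near=0.1, vgap_far=50.0)


def clean_config(name, **overrides):
    """Noise-free, jitter-free preset with depth room for 6 strides."""
    kw = dict(noise_sd=0.0, timestamp_jitter_sd=0.0, start_depth=12.0, seed=7)
    kw.update(overrides)
    return dataclasses.replace(preset(name), **kw)


@pytest.fixture(scope="session")
def healthy_clean():
    cfg = clean_config("healthy")
    traj, truth = simulate_walk(cfg, n_strides=6)
    return cfg, traj, truth


@pytest.fixture(scope="session")
def hemiplegic_clean():
    cfg = clean_config("hemiplegic")
    traj, truth = simulate_walk(cfg, n_strides=6)
    return cfg, traj, truth


@pytest.fixture(scope="session")
def healthy_result(healthy_clean):
    cfg, traj, truth = healthy_clean
    return cfg, truth, run_trial(traj, RunConfig(segmentation=WIDE_VGAP))


@pytest.fixture(scope="session")
def hemiplegic_result(hemiplegic_clean):
    cfg, traj, truth = hemiplegic_clean
    return cfg, truth, run_trial(traj, RunConfig(segmentation=WIDE_VGAP))
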