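import dataclasses

import numpy as np
import pytest

from flowparse.config import ModelConfig
from flowparse.experiments import (RunConfig, run_condition, sim1_conditions,
                                   sim2_conditions, sim3_conditions)
from flowparse.stimuli import ProbeSpec, SceneSpec


# ---------------------------------------------------------------------------
# shared full-resolution campaign runs (computed once per session)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def rc64():
    return RunConfig(model=ModelConfig(), rng_seed=0)


@pytest.fixture(scope="session")
def sim1_results(rc64):
    return {c.name: run_condition(rc64, c)
            for c in sim1_conditions(rc64.rng_seed)}


@pytest.fixture(scope="session")
def sim2_results(rc64):
    return {c.name: run_condition(rc64, c)
            for c in sim2_conditions(rc64.rng_seed)}


@pytest.fixture(scope="session")
def sim3_full_result(rc64):
    conds = {c.name: c for c in sim3_conditions(rc64.rng_seed)}
    return run_condition(rc64, conds["sim3_full"])


@pytest.fixture(scope="session")
def sim3_series_results(rc64, sim3_full_result):
    """The stereo self-motion speed series (Full condition)."""
    conds = {c.name: c for c in sim3_conditions(rc64.rng_seed)}
    out = {"sim3_full": sim3_full_result}
    for name in ("sim3_full_c1.6", "sim3_full_c2.6", "sim3_full_c3.6",
                 "sim3_full_c4.6"):
        out[name] = run_condition(rc64, conds[name])
    return out


@pytest.fixture(scope="session")
def cfg32():
    """Reduced-resolution config for fast qualitative runs."""
    return ModelConfig().scaled(32)


@pytest.fixture(scope="session")
def cfg64():
    return ModelConfig()


@pytest.fixture
def fronto_scene():
    return SceneSpec(scenario="frontoparallel", component_speed_at_probe=1.0,
                     self_motion_speed=0.5, rng_seed=7)


@pytest.fixture
def fronto_probe():
    return ProbeSpec(offset_from_foe=(0.0, -4.0), object_speed=6.0,
                     object_direction=0.0, onset=0.0, offset=1.0)


@pytest.fixture
def ground_scene():
    return SceneSpec(scenario="ground", component_speed_at_probe=1.0,
                     self_motion_speed=5.7, depth_range=(0.56, 25.0),
                     rng_seed=7)


@pytest.fixture
def ground_probe():
    return ProbeSpec(offset_from_foe=(0.0, -2.0), object_speed=2.5,
                     object_direction=0.0, onset=0.0, offset=1.0)


@pytest.fixture
def cloud_scene():
    return SceneSpec(scenario="cloud", component_speed_at_probe=2.0,
                     self_motion_speed=0.30, depth_range=(0.69, 1.03),
                     stereo=True, n_points=480, rng_seed=7)


@pytest.fixture
def cloud_probe():
    return ProbeSpec(offset_from_foe=(4.0, 0.0), object_speed=2.0,
                     object_direction=90.0, onset=0.8, offset=1.0, depth=0.86)


def replace(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
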