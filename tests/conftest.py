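import numpy as np
import pytest

from palmsust.grid import GridGeometry
from palmsust.scene import SceneConfig, WaterBodySpec, generate_scene


@pytest.fixture(scope="session")
def default_bundle():
    """Default-configuration scene, seed 1 (the study-condition fixture)."""
    return generate_scene(SceneConfig(seed=1))


def small_scene_config(seed: int = 7) -> SceneConfig:
    """A quarter-size scene for fast pipeline-level tests."""
    return SceneConfig(
        seed=seed,
        geometry=GridGeometry(0.0, 64.0, 0.25, 256, 256),
        tile_cells=64,
        water_spec=[
            WaterBodySpec(center=(14.0, 50.0), radius_m=6.0, mean_red=70.0),
            WaterBodySpec(center=(50.0, 14.0), radius_m=6.0, mean_red=150.0),
        ],
    )


@pytest.fixture(scope="session")
def small_bundle():
    return generate_scene(small_scene_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
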