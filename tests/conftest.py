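import numpy as np
import pytest

from mitoscreen.synth import EffectSpec, SceneParams, generate_scene


@pytest.fixture(scope="session")
def default_params() -> SceneParams:
    return SceneParams()


@pytest.fixture(scope="session")
def null_scene(default_params):
    """One default confluent scene with ground truth (seed fixed)."""
    truth, rasters = generate_scene(default_params, EffectSpec.null(), 7)
    return truth, rasters


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
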