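import numpy as np
import pytest

from pigtag import scene_synth as ss
from pigtag.detect import DetectorConfig, make_reference_backends


@pytest.fixture(scope="session")
def backends():
    return make_reference_backends()


@pytest.fixture(scope="session")
def cfg():
    return DetectorConfig()


@pytest.fixture(scope="session")
def clean_scene():
    """One deterministic clean scene with its ground truth."""
    spec = ss.SceneSpec(n_pigs=3, seed=7)
    img, truth = ss.render_scene(spec)
    return spec, img, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
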