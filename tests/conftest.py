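import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    from birdparts.detector import NetworkConfig

    return NetworkConfig(num_classes=32, width_multiple=0.125,
                         depth_multiple=1 / 12, input_size=160, seed=7)


@pytest.fixture(scope="session")
def tiny_network(tiny_config):
    from birdparts.detector import build_network

    return build_network(tiny_config)


@pytest.fixture(scope="session")
def scene_dataset(tmp_path_factory):
    """Small rendered scene dataset shared across tests (8 species)."""
    from birdparts.synthetic_data import SceneSpec, generate_scenes

    root = tmp_path_factory.mktemp("scenes")
    spec = SceneSpec(n_species=8, seed=21)
    manifest, truth = generate_scenes(spec, 12, root, split="train")
    return spec, manifest, truth, root
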