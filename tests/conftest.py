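import numpy as np
import pytest
from hypothesis import settings

from crequant.atlas import AtlasSpec, build_toy_atlas, midlevel_partition

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_atlas():
    """The default 12-division x 4-leaf toy atlas (2.5 mm rostro-caudal)."""
    ontology, annotation = build_toy_atlas(AtlasSpec())
    partition = midlevel_partition(ontology, annotation)
    return ontology, annotation, partition


@pytest.fixture(scope="session")
def small_atlas():
    """A 4-division x 2-leaf atlas small enough for brute-force oracles."""
    spec = AtlasSpec(
        n_divisions=4, leaves_per_division=2, shape=(20, 20, 32),
        voxel_size_um=25.0, margin_voxels=2, seed=3,
    )
    ontology, annotation = build_toy_atlas(spec)
    partition = midlevel_partition(ontology, annotation)
    return ontology, annotation, partition


@pytest.fixture
def rng():
    return np.random.default_rng(20140710)
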