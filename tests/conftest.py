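import numpy as np
import pytest

from fastfc import PlantedStructureSpec, make_timeseries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_dataset():
    """One planted 20-voxel cluster (within-correlation 0.7) among 200 voxels,
    T=275 scans: the shared end-to-end recovery fixture."""
    spec = PlantedStructureSpec(V=200, T=275, clusters=((20, 0.7),), seed=0)
    ts, labels = make_timeseries(spec)
    return spec, ts, labels
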