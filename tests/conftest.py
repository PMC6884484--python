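import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gplf import (Atlas, GPLFModel, PhantomSpec, SelectionConfig, ShapeSpec,
                  WarpSpec, make_phantom, make_warped_atlases)

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


SMALL_SPEC = PhantomSpec(
    grid_shape=(28, 28, 8), spacing=(1.0, 1.0, 1.5),
    tissue_shapes=(
        ShapeSpec("ellipsoid", (14.0, 14.0, 4.0), (12.0, 12.0, 3.6), 0.35),
        ShapeSpec("ellipsoid", (14.0, 13.0, 4.0), (5.0, 5.0, 2.0), 0.60),
    ),
    noise_sigma=0.03,
)


@pytest.fixture(scope="session")
def small_truth():
    """A compact phantom (28x28x8) with its target-structure label."""
    return make_phantom(SMALL_SPEC, seed=11)


@pytest.fixture(scope="session")
def small_atlases(small_truth):
    """Four warped atlases derived from the small phantom."""
    return make_warped_atlases(small_truth, WarpSpec(n_atlases=4, seed=12))


@pytest.fixture(scope="session")
def small_selection():
    return SelectionConfig(sr=3.0, top_k=60, patch_shape=(5, 5, 3))


@pytest.fixture(scope="session")
def fitted_small(small_atlases, small_selection):
    """A trained GP-LF model on the small fixture (shared across tests)."""
    model = GPLFModel(small_atlases, tissue="thalamus", selection=small_selection)
    return model.fit(max_sweeps=3)


@pytest.fixture
def identical_atlases():
    """Three byte-identical noiseless atlases: the trivial-fusion fixture."""
    spec = PhantomSpec(
        grid_shape=(16, 16, 6), spacing=(1.0, 1.0, 1.5),
        tissue_shapes=(
            ShapeSpec("ellipsoid", (8.0, 8.0, 3.0), (7.0, 7.0, 2.8), 0.35),
            # a brighter companion keeps the target mid-intensity, so its
            # histogram spike sits in an interior bin
            ShapeSpec("ellipsoid", (6.0, 11.0, 3.0), (1.5, 1.5, 1.2), 0.85),
            ShapeSpec("ellipsoid", (8.0, 8.0, 3.0), (3.5, 3.5, 1.5), 0.60),
        ),
        noise_sigma=0.0)
    intens, label = make_phantom(spec, seed=0)
    atlases = [Atlas(f"a{i}", intens, label) for i in range(3)]
    return intens, label, atlases


def random_mask_pair(rng, shape=(7, 6, 5), max_voxels=30):
    """Two random voxel sets of at most max_voxels each, as label arrays."""
    out = []
    for _ in range(2):
        n = int(rng.integers(1, max_voxels + 1))
        flat = rng.choice(np.prod(shape), size=n, replace=False)
        arr = np.zeros(np.prod(shape), dtype=np.uint8)
        arr[flat] = 1
        out.append(arr.reshape(shape))
    return out[0], out[1]
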