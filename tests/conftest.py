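import numpy as np
import pytest

from pddc.phantom import PhantomSpec, make_phantom, random_phantom_spec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_subject():
    """One deterministic phantom with a known CMB, lacune and vein."""
    fov_mid = (63.0, 63.0, 31.0)
    spec = PhantomSpec(
        grid_shape=(64, 64, 32),
        voxel_spacing=(2.0, 2.0, 2.0),
        cmb_specs=[((40.0, 40.0, 30.0), 4.0, 0.75)],
        vein_specs=[([(20.0, 80.0, 20.0), (80.0, 80.0, 40.0)], 2.0, 0.6)],
        lacune_specs=[((80.0, 40.0, 30.0), 8.0)],
        noise_sigma=0.01,
        seed=7,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def benchmark_subjects():
    """Twenty seeded phantoms with >= 3 mm lesions for recovery benchmarks."""
    return [make_phantom(random_phantom_spec(seed)) for seed in range(20)]
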