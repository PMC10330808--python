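import numpy as np
import pytest

from mssfseg.phantoms import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(image_size=64, root_width_px=2.5,
                       target_vessel_frac_range=(0.05, 0.15))


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """One deterministic 64x64 phantom (image, gt, fov)."""
    return generate_phantom(small_spec, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
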