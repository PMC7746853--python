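import numpy as np
import pytest

from acbf.phantom import LesionSpec, PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Two-valued 128x128 phantom: one smooth ellipse lesion, no speckle."""
    spec = PhantomSpec(
        noise_sigma=0.0,
        lesions=(LesionSpec(center=(64.0, 64.0), radii=(20.0, 16.0), perturb_amp=0.0, rotation=0.3),),
    )
    image, mask = make_phantom(spec)
    return image, mask, spec


@pytest.fixture(scope="session")
def speckled_phantom():
    """Default-noise phantom with a perturbed lesion margin."""
    spec = PhantomSpec(seed=3)
    image, mask = make_phantom(spec)
    return image, mask, spec


@pytest.fixture(scope="session")
def bimodal32_base() -> PhantomSpec:
    """Base spec of the small bimodal suite used for cross-model checks.

    Strong contrast (0.2 vs 0.8) and a lesion large relative to the
    32x32 frame keep every jittered phantom inside the operating
    envelope of the unit-weight curvature penalty.
    """
    return PhantomSpec(
        height=32,
        width=32,
        lesions=(LesionSpec(center=(16.0, 16.0), radii=(9.0, 7.5), perturb_amp=0.5),),
        background_level=0.8,
        lesion_level=0.2,
        noise_sigma=0.05,
        psf_sigma=1.0,
    )
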