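import numpy as np
import pytest

from wvt import synthetic


@pytest.fixture(scope="session")
def ring_target():
    """Shared structured calibration target (rings + spokes), 256 px at 0.32 μm."""
    return synthetic.make_ring_target(shape=(256, 256), pixel_size_um=0.32, seed=0)


@pytest.fixture(scope="session")
def coronal_phantom():
    """One seeded coronal section with ground truth."""
    return synthetic.make_coronal_section(seed=5)


@pytest.fixture(scope="session")
def small_phantom_brain():
    """A 5-layer tapered phantom brain, desk scale."""
    spec = synthetic.PhantomSpec(seed=7, n_layers=5, shape=(350, 500),
                                 max_semi_axes_um=(330.0, 230.0),
                                 n_green_somas=400, n_red_somas=350,
                                 coloc_fraction=0.01)
    return synthetic.generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
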