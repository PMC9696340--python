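import numpy as np
import pytest

import dissolvis as dv
from dissolvis import phantom


@pytest.fixture(scope="session")
def tiny_spec() -> dv.PhantomSpec:
    """Small tablet (~48^2 x 19 grid) for fast structural tests."""
    return dv.PhantomSpec(seed=3).scaled(
        0.082, pore_radius_mean_um=70.0, pore_radius_sd_um=10.0, margin_vox=3
    )


@pytest.fixture(scope="session")
def tiny_phantom(tiny_spec):
    return dv.build_tablet(tiny_spec)


@pytest.fixture(scope="session")
def clean_spec() -> dv.PhantomSpec:
    """Same geometry imaged without PSF blur or noise (idealized scanner)."""
    return dv.PhantomSpec(seed=3, psf_sigma_vox=0.0, noise_sd=0.0).scaled(
        0.082, pore_radius_mean_um=70.0, pore_radius_sd_um=10.0, margin_vox=3
    )


@pytest.fixture(scope="session")
def clean_phantom(clean_spec):
    return dv.build_tablet(clean_spec)


@pytest.fixture(scope="session")
def clean_series(clean_spec, clean_phantom):
    dry, truth = clean_phantom
    series = phantom.simulate_ingress(dry, truth, clean_spec, [0.0, 2.0, 4.0, 8.0])
    return series, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
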