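import numpy as np
import pytest

from fedpet.phantom import CenterProfile, Ellipse, PhantomSpec


@pytest.fixture
def disc_spec():
    """Uniform soft-tissue disc, radius 100 mm, on a 128-px 2 mm grid."""
    return PhantomSpec(
        grid_size=128,
        pixel_size_mm=2.0,
        body=Ellipse((0.0, 0.0), (100.0, 100.0)),
        body_activity=1.0,
        background_mu=0.0096,
    )


@pytest.fixture
def small_body_spec():
    """A small elliptical body fitting a 64-px 3 mm grid."""
    return PhantomSpec(
        grid_size=64,
        pixel_size_mm=3.0,
        body=Ellipse((0.0, 0.0), (70.0, 55.0)),
        body_activity=1.0,
        background_mu=0.0096,
    )


@pytest.fixture
def quiet_profile():
    """A center with every corruption switched off except the matrix size."""
    return CenterProfile(
        center_id="quiet",
        psf_fwhm_mm=0.0,
        noise_scale=0.0,
        scatter_fraction=0.0,
        matrix_size=64,
        n_studies=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
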