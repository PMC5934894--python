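import dataclasses

import numpy as np
import pytest

from petmtv.phantom import LesionSpec, PhantomSpec, generate_phantom, reference_phantom_suite


@pytest.fixture(scope="session")
def suite():
    """Reference phantom fixtures keyed by name: (spec, expected)."""
    return {name: (spec, expected) for name, spec, expected in reference_phantom_suite()}


def _noiseless(spec):
    return dataclasses.replace(spec, psf_fwhm_mm=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def plateau_cube(suite):
    """Noiseless, unblurred cube phantom: image takes exactly {1, 10}."""
    spec, _ = suite["cube"]
    return generate_phantom(_noiseless(spec))


@pytest.fixture(scope="session")
def plateau_two_lesion(suite):
    spec, _ = suite["two_lesion"]
    return generate_phantom(_noiseless(spec))


@pytest.fixture(scope="session")
def blurred_sphere(suite):
    spec, _ = suite["calibration_sphere"]
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def blurred_two_lesion(suite):
    spec, _ = suite["two_lesion"]
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def gradient_phantom(suite):
    spec, _ = suite["gradient_sphere"]
    return generate_phantom(spec)


@pytest.fixture
def small_plateau():
    """A tiny (16^3) two-plateau phantom for exhaustive-oracle tests."""
    spec = PhantomSpec(
        grid_shape=(16, 16, 16),
        spacing=(4.0, 4.0, 4.0),
        background_suv=1.0,
        lesions=(
            LesionSpec(shape="sphere", center_mm=(24.0, 24.0, 32.0), size_mm=(18.0,), uptake_suv=8.0),
            LesionSpec(shape="sphere", center_mm=(48.0, 44.0, 32.0), size_mm=(14.0,), uptake_suv=5.0),
        ),
        psf_fwhm_mm=0.0,
        noise_sd=0.08,
        seed=5,
    )
    return generate_phantom(spec)
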