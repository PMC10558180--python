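import numpy as np
import pytest

from tumorburden.core import BinaryMask, GridGeometry, ScalarVolume
from tumorburden.phantom import PhantomSpec, generate_cohort, generate_phantom


def random_mask(rng: np.random.Generator, shape, spacing, p=0.3, origin=None) -> BinaryMask:
    geometry = GridGeometry(shape=shape, spacing=spacing,
                            origin=origin if origin is not None else (0.0,) * len(shape))
    return BinaryMask(geometry=geometry, values=rng.random(shape) < p)


def random_volume(rng: np.random.Generator, shape, spacing) -> ScalarVolume:
    geometry = GridGeometry(shape=shape, spacing=spacing)
    return ScalarVolume(geometry=geometry, values=rng.random(shape))


@pytest.fixture(scope="session")
def clean_phantom():
    """Degenerate generator: no noise, no PSF blur, full T2 detection —
    every modality should reproduce the ground truth exactly."""
    spec = PhantomSpec(noise_sd_mri=0.0, noise_sd_pet=0.0, noise_sd_fluor=0.0,
                       pet_psf_fwhm=0.0, t2_detect_fraction=1.0, gd_status=True,
                       infiltration_width=0.0, seed=11)
    return generate_phantom(spec, case_id="clean")


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default study-condition phantom (noise, PSF blur, partial T2)."""
    return generate_phantom(PhantomSpec(seed=23), case_id="noisy")


@pytest.fixture(scope="session")
def cohort():
    """Default 4/5/4 cohort at the study's stratum composition."""
    return generate_cohort(master_seed=7)
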