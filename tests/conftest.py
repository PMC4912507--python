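"""Shared fixtures: toy objects and the session-scoped desk study."""

import numpy as np
import pytest

from cardiacpvc.image import Image
from cardiacpvc.phantom import PhantomParams, build_phantom
from cardiacpvc.projector import (SinogramGeometry, attenuation_factors,
                                  simulate_acquisition)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160617)


@pytest.fixture(scope="session")
def desk_phantom():
    """Desk-scale thorax phantom (96^3 voxels at 2 mm)."""
    return build_phantom(PhantomParams.desk())


@pytest.fixture(scope="session")
def heart_fov_phantom():
    """Full-resolution (0.8 mm) phantom on a heart-centred field of view."""
    return build_phantom(PhantomParams(shape=(160, 160, 120)))


def disc_annulus(n=64, voxel=2.0, annulus=10.0, disc=4.0):
    """2-D hot annulus (myocardium-like) around a warm disc (blood-like)."""
    img = Image(np.zeros((n, n, 1)), (voxel, voxel, voxel), "kBq/cc")
    x, y, _ = img.coord_grids()
    r = np.sqrt(x ** 2 + y ** 2)
    ann = (r >= 18) & (r <= 30)
    dsc = r < 12
    img.data[ann] = annulus
    img.data[dsc] = disc
    mu = Image(np.where(r <= 40, 0.096, 0.0), (voxel, voxel, voxel), "cm^-1")
    return img, mu, ann, dsc


@pytest.fixture(scope="session")
def annulus_toy():
    return disc_annulus()


@pytest.fixture(scope="session")
def noisy_toy_sinogram(annulus_toy):
    """Poisson data + attenuation factors for the annulus toy."""
    from cardiacpvc.projector import poisson_realizations
    act, mu, ann, dsc = annulus_toy
    geom = SinogramGeometry(24, 52, 2.0)
    expected = simulate_acquisition(act, mu, geom, None, 2e5)
    acf = attenuation_factors(mu, geom)
    noisy = poisson_realizations(expected, 1, 7)[0]
    return expected, noisy, acf


@pytest.fixture(scope="session")
def desk_study():
    """The scaled-down end-to-end study (10 noise realizations, 64^3 grid).

    One shared run feeds the ensemble-level checks: algorithm ordering,
    significance testing, polar-map contracts.
    """
    from cardiacpvc.pipeline import StudyConfig, run_study
    return run_study(StudyConfig(n_realizations=10))
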