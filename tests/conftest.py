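import numpy as np
import pytest

from perfph.config import PhantomConfig
from perfph.io import CestAcquisition
from perfph import synthetic as syn


@pytest.fixture(scope="session")
def offsets():
    return syn.offset_schedule()


def build_acquisition(acidity, b0, offsets, noise_sd=0.0, rng=None) -> CestAcquisition:
    """CestAcquisition from per-voxel acidity/B0 arrays via the z-spectrum
    generator (arrays share one 3D shape)."""
    acidity = np.asarray(acidity, dtype=float)
    b0 = np.broadcast_to(np.asarray(b0, dtype=float), acidity.shape)
    shape = acidity.shape
    spec, s0 = syn.simulate_zspectrum(acidity.ravel(), b0.ravel(), offsets, noise_sd, rng)
    return CestAcquisition(
        offsets=offsets,
        saturated=spec.reshape(shape + (offsets.size,)),
        s0=np.asarray(s0).reshape(shape),
        mask=np.ones(shape, dtype=bool),
    )


@pytest.fixture(scope="session")
def noisefree_config():
    """Small cohort with every noise source off and a flat B0 field."""
    return PhantomConfig(
        n_subjects=3, grid_shape=(20, 20, 10), n_timepoints=40,
        noise_sd_dsc=0.0, noise_sd_cest=0.0, link_noise_sd=0.0,
        b0_amplitude_ppm=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def noisefree_bundle(noisefree_config):
    return syn.simulate_subject(noisefree_config, 0)


@pytest.fixture(scope="session")
def noisefree_cohort(noisefree_config):
    return syn.simulate_cohort(noisefree_config)
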