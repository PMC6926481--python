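import numpy as np
import pytest

from chromaclock import photometry as ph


@pytest.fixture(scope="session")
def grid():
    return ph.DEFAULT_GRID


@pytest.fixture(scope="session")
def receptors():
    """Lens-corrected red-cone mouse opsin set on the default grid."""
    return ph.mouse_photoreceptors()


@pytest.fixture(scope="session")
def receptors_no_lens():
    return ph.mouse_photoreceptors(lens=ph.LensTransmission.identity())


@pytest.fixture(scope="session")
def rgb_uv_basis():
    """Synthetic 385/460/630 nm Gaussian-primary basis, 20 nm FWHM."""
    spds = [ph.gaussian_primary(p, 20.0, 1e15) for p in (385.0, 460.0, 630.0)]
    return ph.PrimaryBasis(tuple(spds), ("385nm", "460nm", "630nm"))
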