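import numpy as np
import pytest

from icdbind import (
    Spectrum,
    Unit,
    fenoprofen_like,
    generate_titration,
    generate_toy_cyclodextrin,
)


@pytest.fixture
def gaussian_band():
    """Symmetric Gaussian band centred at 284.5 nm on a 0.5 nm grid."""
    wl = np.arange(250.0, 320.5, 0.5)
    vals = 2.0 * np.exp(-0.5 * ((wl - 284.5) / 6.0) ** 2)
    return Spectrum(wl, vals, Unit.DELTA_ABSORBANCE)


@pytest.fixture
def toy_host():
    return generate_toy_cyclodextrin()


@pytest.fixture
def clean_titration():
    """Noiseless fenoprofen-like CD+UV titration (true logK = 3.06)."""
    return generate_titration(fenoprofen_like())


def random_rigid_motion(rng):
    """A uniformly random rotation (QR-based) plus a random translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-20.0, 20.0, 3)
    return Q, t
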