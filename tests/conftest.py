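import warnings

import numpy as np
import pytest

from pseudoprog.synthetic import PhantomCase, generate_phantom_case

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_phantom():
    """One zero-noise phantom at the TP+mixed group-mean feature triple."""
    return generate_phantom_case(PhantomCase())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
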