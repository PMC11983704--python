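import numpy as np
import pytest

from vibronic2pa import (
    SyntheticSpec,
    compute_normal_modes,
    generate_model_system,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def gen_default():
    """A default 6-mode synthetic system (session-scoped: generation is
    deterministic and read-only)."""
    return generate_model_system(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def gen_basis(gen_default):
    return compute_normal_modes(gen_default.ground)


def random_rotation(rng) -> np.ndarray:
    """A Haar-ish random proper rotation matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
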