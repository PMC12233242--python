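import numpy as np
import pytest

from dentalign.synthetic_arch import generate_arch_case


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def default_case():
    """One standard 14-tooth case at default severity."""
    return generate_arch_case(rng_seed=11)


@pytest.fixture(scope="session")
def zero_severity_case():
    """A case whose malocclusion state already equals the target."""
    return generate_arch_case(malocclusion_severity=(0.0, 0.0), rng_seed=11)


@pytest.fixture(scope="session")
def small_case_set():
    """Twenty default-severity cases for training smoke tests."""
    return [generate_arch_case(rng_seed=100 + i, case_id=f"fix{i:02d}") for i in range(20)]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR-based, det fixed to +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
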