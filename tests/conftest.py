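import numpy as np
import pytest

from fetalvol import SegmentMask, default_study_spec, generate_phantom


def sphere_mask(radius: float, pad: int = 5) -> np.ndarray:
    n = int(2 * np.ceil(radius) + 2 * pad + 1)
    c = (n - 1) / 2.0
    g = np.arange(n)
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    return (xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= radius**2


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def sphere10():
    return SegmentMask(sphere_mask(10.0), organ_label="heart")


@pytest.fixture(scope="session")
def default_phantom():
    """One default-subject phantom (speckle sigma 0.1), shared across tests."""
    spec = default_study_spec(1, 7)[0]
    return generate_phantom(spec)
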