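import numpy as np
import pytest

from wisdom.wishart import SPDMatrix, validate_spd


def random_spd(rng: np.random.Generator, p: int, scale: float = 1.0) -> np.ndarray:
    """Random SPD matrix as G G' + small diagonal, G square Gaussian."""
    g = rng.standard_normal((p, p))
    return scale * (g @ g.T + 0.1 * np.eye(p))


def random_spd_validated(rng: np.random.Generator, p: int) -> SPDMatrix:
    return validate_spd(random_spd(rng, p))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
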