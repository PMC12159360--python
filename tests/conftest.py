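import numpy as np
import pytest

from uasswath.patternator import PatternatorProfile


@pytest.fixture
def box_profile():
    """Uniform profile: 10 grooves of 0.1 m pitch, extent 1.0 m."""
    return PatternatorProfile(
        positions=np.arange(10) * 0.1, volumes=np.ones(10), pitch=0.1
    )


@pytest.fixture
def triangle_profile():
    """Symmetric triangular profile of base 2 m on a 0.1 m grid."""
    pos = np.arange(-10, 11) * 0.1
    return PatternatorProfile(
        positions=pos, volumes=np.maximum(0.0, 1.0 - np.abs(pos)), pitch=0.1
    )


def random_profile(rng: np.random.Generator) -> PatternatorProfile:
    """Random multimodal synthetic profile for cross-check sweeps."""
    n_plumes = int(rng.integers(1, 5))
    offsets = np.sort(rng.uniform(-1.5, 1.5, size=n_plumes))
    sigma = float(rng.uniform(0.2, 0.8))
    lo, hi = offsets.min() - 3 * sigma, offsets.max() + 3 * sigma
    pos = np.arange(np.floor(lo / 0.1), np.ceil(hi / 0.1) + 1) * 0.1
    vol = np.zeros_like(pos)
    for mu in offsets:
        vol += np.exp(-0.5 * ((pos - mu) / sigma) ** 2)
    vol *= rng.uniform(0.7, 1.3, size=vol.size)  # groove-level noise
    return PatternatorProfile(positions=pos, volumes=vol, pitch=0.1)
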