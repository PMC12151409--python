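import numpy as np
import pytest

from oart import OartConfig, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Desk-scale generator spec for fast unit tests."""
    return SyntheticSpec(
        n_acceptable=40,
        n_anomalous=6,
        m_features=60,
        n_planted_per_category=5,
        seed=7,
    )


@pytest.fixture
def small_config():
    """Reduced grid/rounds for fast unit tests."""
    return OartConfig(
        n_rounds=6, sigma_grid=(0.05, 0.15, 0.3, 0.6, 0.9), seed=7
    )


def scalar_round_oracle(column, sequence, sigma, alpha):
    """Independent per-feature simulation of one training round.

    The resonance dynamics are per-feature, so running a single feature as a
    scalar recursion over the same presentation order must reproduce the
    vectorized result exactly (bitwise).
    """
    z = float(column[sequence[0]])
    f = True
    for idx in sequence[1:]:
        if not f:
            break
        x = float(column[idx])
        if abs(x - z) <= sigma:
            z = (1.0 - alpha) * z + alpha * x
        else:
            f = False
    return f, z
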