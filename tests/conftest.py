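import numpy as np
import pytest

from coralmound.chronology import CoralDate


@pytest.fixture
def printed_dates():
    """The six main-text coral dates of the study core (depth cm, age ka, 2SD)."""
    return [
        CoralDate(12, 1.64, 0.04),
        CoralDate(24, 1.44, 0.02),
        CoralDate(89, 2.37, 0.03),
        CoralDate(193, 2.89, 0.02),
        CoralDate(207, 3.18, 0.03),
        CoralDate(212, 4.13, 0.04),
    ]


@pytest.fixture
def small_phantom():
    """Small seeded CT phantom with per-slice truth (percent)."""
    from coralmound.synthetic import gen_ct_phantom

    return gen_ct_phantom(11, shape=(36, 48, 48), target_fraction=0.07)


@pytest.fixture
def envelope_grid():
    """Deterministic 100-point grid spanning the EOS-80 validity envelope."""
    rng = np.random.default_rng(42)
    s = rng.uniform(0, 42, 100)
    t = rng.uniform(-2, 40, 100)
    p = rng.uniform(0, 12000, 100)
    return s, t, p
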