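import numpy as np
import pytest

from clockscreen.dam_io import FlySeries, MINUTES_PER_DAY


def make_day_series(prefix, fill=1.0, fly_id="fly", genotype="g") -> FlySeries:
    """A one-day FlySeries whose first minutes are ``prefix`` and whose
    remainder is ``fill`` (active, so it never extends a sleep run)."""
    counts = np.full(MINUTES_PER_DAY, fill, dtype=float)
    counts[:len(prefix)] = prefix
    return FlySeries(fly_id=fly_id, genotype=genotype, counts=counts,
                     day_seg=["LD"], day_ids=[0])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ref3():
    from clockscreen.synth import make_synthetic_reference
    return make_synthetic_reference(n_guides=3, seed=7)


@pytest.fixture(scope="session")
def ref1():
    from clockscreen.synth import make_synthetic_reference
    return make_synthetic_reference(n_guides=1, seed=7)
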