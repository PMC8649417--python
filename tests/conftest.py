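import numpy as np
import pytest

from grmcompare.model import ItemParameters, LatentGrid
from grmcompare.simulate import build_item_bank


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def grid():
    return LatentGrid.default()


@pytest.fixture
def toy_items():
    """A small mixed item set with known, hand-checkable parameters."""
    return [
        ItemParameters(5, 2.0, [-1.2, -0.3, 0.6, 1.5]),
        ItemParameters(2, 1.1, [0.4]),
        ItemParameters(5, 0.7, [-2.0, -0.9, 0.1, 1.0]),
    ]


@pytest.fixture(scope="session")
def small_banks():
    """Reduced-size banks (shared across tests to amortise generation)."""
    out = {}
    for i, (item_type, level) in enumerate(
        (t, l)
        for t in ("dichotomous", "polytomous")
        for l in ("high", "low")
    ):
        out[(item_type, level)] = build_item_bank(
            item_type, level, size=2000, rng=np.random.default_rng(500 + i)
        )
    return out


def random_item(rng) -> ItemParameters:
    V = int(rng.choice([2, 5]))
    a = float(rng.uniform(0.3, 3.5))
    b = np.sort(rng.uniform(-3, 3, size=V - 1))
    while V > 2 and np.any(np.diff(b) <= 1e-3):
        b = np.sort(rng.uniform(-3, 3, size=V - 1))
    return ItemParameters(V, a, b)
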