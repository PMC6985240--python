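import numpy as np
import pytest

from qpop import (
    Drug,
    DrugPanel,
    build_oacd,
    fixture_panel,
    planted_truth,
)
from qpop.surface import QuadraticSurface


def make_panel(n, L=2):
    """Small synthetic panel with doubling concentrations."""
    return DrugPanel(
        tuple(
            Drug(
                name=f"d{i}",
                concentrations=(0.0, *[0.1 * 2**j * (i + 1) for j in range(L)]),
            )
            for i in range(n)
        )
    )


def random_surface(panel, rng, scale=0.2):
    n = panel.n
    return QuadraticSurface(
        panel=panel,
        beta0=1.0,
        beta_lin=rng.normal(0, scale, n),
        beta_quad=rng.normal(0, scale / 2, n),
        beta_int=rng.normal(0, scale / 2, n * (n - 1) // 2),
    )


@pytest.fixture
def panel11():
    return fixture_panel(11)


@pytest.fixture
def panel4():
    return make_panel(4)


@pytest.fixture
def oacd11(panel11):
    return build_oacd(panel11, seed=0)


@pytest.fixture
def truth11(panel11):
    return planted_truth(panel11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
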