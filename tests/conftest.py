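import numpy as np
import pytest

from segpol import GridSpec, build_grid, build_model, initial_condition


@pytest.fixture(scope="session")
def grid_1x4():
    return build_grid(GridSpec(1, 4))


@pytest.fixture(scope="session")
def model_1x4(grid_1x4):
    """Default-parameter guarded 1x4 model (also warms the compiled RHS)."""
    return build_model(grid_1x4)


@pytest.fixture(scope="session")
def crisp_ic(grid_1x4):
    return initial_condition("crisp", grid_1x4)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


class StubModel:
    """Duck-typed stand-in for ODESystem exposing toy right-hand sides."""

    def __init__(self, f, n_states):
        self.n_states = n_states
        self._f = f

    def rhs(self, t, y):
        return np.asarray(self._f(np.asarray(y, dtype=float)), dtype=float)

    def odeint_rhs(self, y, t):
        return self.rhs(t, y)


@pytest.fixture()
def stub_model():
    return StubModel
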