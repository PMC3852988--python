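import numpy as np
import pytest

from sharksdm import EnvStack, Grid, ScenarioConfig, make_scenario


def make_grid(values, mask=None, cell_size=2500.0, x0=0.0, y0=0.0):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return Grid(values=values, mask=np.asarray(mask, bool), x_origin=x0, y_origin=y0,
                cell_size=cell_size)


@pytest.fixture
def small_grid():
    return make_grid(np.arange(12, dtype=float).reshape(3, 4))


@pytest.fixture(scope="session")
def signal_scenario():
    """Single-month signal scenario with uniform effort, 200 presences."""
    cfg = ScenarioConfig(
        monthly_n={"July": 200}, months=("July",), effort_bias=False
    )
    return make_scenario(cfg, seed=7)


@pytest.fixture(scope="session")
def null_scenario():
    """Uniform-truth scenario (no environmental signal), 200 presences."""
    cfg = ScenarioConfig(
        monthly_n={"July": 200}, months=("July",), coefficients={}, effort_bias=False
    )
    return make_scenario(cfg, seed=7)


@pytest.fixture(scope="session")
def tiny_stack():
    """A 24x24 two-variable-style stack for fast feature/fit tests."""
    rng = np.random.default_rng(3)
    shape = (24, 24)
    depth = 10 + 240 * np.linspace(0, 1, shape[1])[None, :] * np.ones(shape)
    chl = np.exp(0.3 * rng.standard_normal(shape) + 1.0)
    sst = 12 + 2 * np.linspace(0, 1, shape[0])[:, None] * np.ones(shape)
    layers = {
        "depth": make_grid(depth),
        "chl_a": make_grid(chl),
        "sst": make_grid(sst),
    }
    return EnvStack("July", layers)
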