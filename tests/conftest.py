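import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from senpop.synthetic_data import fixture_catalog

settings.register_profile(
    "senpop",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("senpop")


@pytest.fixture(scope="session")
def catalog():
    return fixture_catalog()


@pytest.fixture(scope="session")
def wi38_irr(catalog):
    return catalog["WI38_irradiation"]


@pytest.fixture(scope="session")
def mrc5_irr(catalog):
    return catalog["MRC5_irradiation"]


@pytest.fixture(scope="session")
def wi38_rep(catalog):
    return catalog["WI38_replicative"]


@pytest.fixture(scope="session")
def bj_rep(catalog):
    return catalog["BJ_replicative"]


@pytest.fixture(scope="session")
def mrc5_rep(catalog):
    return catalog["MRC5_replicative"]


def rk4(rhs, y0, t_grid, dt):
    """Hand-rolled fixed-step RK4: the independent integration oracle."""
    t_grid = np.asarray(t_grid, dtype=float)
    out = np.empty((len(y0), t_grid.size))
    y = np.asarray(y0, dtype=float)
    t = t_grid[0]
    out[:, 0] = y
    for j, t_next in enumerate(t_grid[1:], start=1):
        while t < t_next - 1e-12:
            h = min(dt, t_next - t)
            k1 = np.asarray(rhs(t, y))
            k2 = np.asarray(rhs(t + h / 2, y + h / 2 * k1))
            k3 = np.asarray(rhs(t + h / 2, y + h / 2 * k2))
            k4 = np.asarray(rhs(t + h, y + h * k3))
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[:, j] = y
        t = t_next
    return out
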