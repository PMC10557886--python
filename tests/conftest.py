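import numpy as np
import pytest

import fapsim
from fapsim.engine import RunConfig, run_all_strategies
from fapsim.synthetic_data import make_life_table, make_survival_table


@pytest.fixture(scope="session")
def params():
    return fapsim.default_params()


@pytest.fixture(scope="session")
def life_table():
    return fapsim.default_life_table()


@pytest.fixture(scope="session")
def survival_table():
    return fapsim.default_survival_table()


@pytest.fixture(scope="session")
def zero_mortality_life_table():
    """A life table with no other-cause mortality before the closure age."""
    lt = make_life_table(0.0, 1e-30, 0.01, 1.0)
    return lt


@pytest.fixture(scope="session")
def perfect_survival_table():
    return make_survival_table((1.0, 1.0, 1.0, 1.0), 0.5)


@pytest.fixture(scope="session")
def zero_disease_params(params):
    """All natural-history transition and entry probabilities zero."""
    p = params.copy()
    p.natural_history.p_polyp_to_preclin_young = 0.0
    p.natural_history.p_polyp_to_preclin_old = 0.0
    for k in p.natural_history.p_preclin_at_entry:
        p.natural_history.p_preclin_at_entry[k] = 0.0
    return p


@pytest.fixture(scope="session")
def small_run_all(params, life_table, survival_table):
    """One shared 20,000-person run of all four strategies (seed 5)."""
    cfg = RunConfig(n=20_000, horizon=40, seed=5)
    return {r.strategy: r for r in run_all_strategies(cfg, params, life_table, survival_table)}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
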