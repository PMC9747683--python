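import numpy as np
import pytest

import entniche as en
from entniche.grids import GridSpec
from entniche.occurrences import presence_cells


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(west=100.0, north=28.0, cell_size=2.5, n_rows=40, n_cols=40)


@pytest.fixture(scope="session")
def stack():
    """Small correlated synthetic stack (shared, read-only)."""
    return en.make_env_stack(n_layers=4, correlation_target=0.3, seed=11)


@pytest.fixture(scope="session")
def truth(stack):
    return en.make_truth(stack, seed=11)


@pytest.fixture(scope="session")
def fitted_env(stack, truth):
    """(presence_env, background_env, truth) dicts for the shared stack."""
    occ = en.sample_presences(truth, 200, seed=12)
    pr, pc = presence_cells(occ, stack.grid)
    rows, cols = np.nonzero(stack.joint_valid())
    rng = np.random.default_rng(13)
    idx = rng.choice(rows.size, 2000, replace=False)
    br, bc = rows[idx], cols[idx]
    names = [n for n in stack.names if n != "elevation"]
    pres = {v: stack.layers[v].values[pr, pc] for v in names}
    bg = {v: stack.layers[v].values[br, bc] for v in names}
    true_bg = truth.suitability.values[br, bc]
    return pres, bg, true_bg


@pytest.fixture(scope="session")
def fitted_model(fitted_env):
    pres, bg, _ = fitted_env
    model, trace = en.fit_maxent(pres, bg, rm=1.0, fc="LQ")
    return model, trace
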