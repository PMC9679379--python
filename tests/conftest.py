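import numpy as np
import pandas as pd
import pytest

import methscore as ms


@pytest.fixture(scope="session")
def planted_cohort() -> ms.syndata.SyntheticCohort:
    """Well-separated 3-cluster cohort with a prognostic latent score."""
    cfg = ms.SimulationConfig(n_samples=150, cluster_shift=2.0, surv_beta=1.0,
                              n_background_genes=400, n_deg_true=60, seed=11)
    return ms.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort() -> ms.syndata.SyntheticCohort:
    """Structureless cohort for type-I-error checks."""
    return ms.simulate_null_cohort(n_samples=40, n_genes=2000, seed=7)


@pytest.fixture()
def tiny_expression() -> pd.DataFrame:
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        rng.normal(8, 1, size=(6, 8)),
        index=[f"G{i}" for i in range(6)],
        columns=[f"S{i}" for i in range(8)],
    )


def naive_breslow_loglik(beta: float, x, time, event) -> float:
    """Independent, deliberately naive Breslow partial log-likelihood used
    as the grid-search oracle for the Cox fits."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for i in range(len(x)):
        if event[i] == 1:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return ll


def grid_maximize(fun, lo=-5.0, hi=5.0, rounds=4, points=200) -> float:
    """Iteratively refined 1-D grid search maximizer."""
    for _ in range(rounds):
        grid = np.linspace(lo, hi, points)
        vals = [fun(b) for b in grid]
        j = int(np.argmax(vals))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, points - 1)]
    return float(grid[j])
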