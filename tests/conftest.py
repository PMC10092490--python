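import numpy as np
import pandas as pd
import pytest

from ternpath.env import EnvParams, EnvSeries, FishParams, HarvestParams, HookCoupling, \
    ResidualCovariance
from ternpath.simulate import TrueParameterSet, default_truth, gen_environment, \
    gen_histories


@pytest.fixture(scope="session")
def tiny_truth():
    """4-year, 2-state toy scenario with no missing years."""
    truth = default_truth(n_years=4, per_year=40, seed=12345)
    truth.missing = {}
    return truth


@pytest.fixture(scope="session")
def tiny_env(tiny_truth):
    return gen_environment(tiny_truth)


@pytest.fixture(scope="session")
def tiny_study(tiny_truth, tiny_env):
    return gen_histories(tiny_truth, tiny_env)


@pytest.fixture()
def flat_env():
    """6-year fully observed series with (effectively) all-zero values --
    a clean slate for analytic mean/likelihood checks.  The landings get a
    negligible o(1e-9) perturbation so that z-scored lag covariates remain
    defined."""
    n = 6
    harvest = np.zeros((n, 3))
    harvest[0, :] = 1e-9
    return EnvSeries(years=np.arange(2000, 2000 + n),
                     sst=np.linspace(19.0, 21.0, n),
                     harvest=harvest, fish=np.zeros((n, 3)),
                     hooks=np.zeros(n))


@pytest.fixture()
def zero_params():
    """All-zero coefficients, unit residual sds, identity covariances."""
    return EnvParams(
        harvest={j: HarvestParams() for j in ("CR", "LI", "TR")},
        fish={k: FishParams() for k in ("MN", "DM", "HR")},
        hooks=HookCoupling(),
        cov=ResidualCovariance(np.eye(3), np.eye(3)),
    )
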