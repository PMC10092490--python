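"""Unit tests for the environmental path sub-model."""

import numpy as np
import pytest
from scipy import stats

from ternpath.env import (
    CovarianceError,
    EnvParams,
    EnvSeries,
    FishParams,
    HarvestParams,
    HookCoupling,
    ResidualCovariance,
    _all_means,
    _covariate_table,
    env_loglik,
    fish_mean,
    harvest_mean,
    harvest_z,
    impute_missing,
    mvn_rows_loglik,
    zstandardize,
)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def test_zstandardize_basic_and_roundtrip():
    z, st = zstandardize([1.0, 2.0, 3.0])
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-12)
    back = st.inverse(z)
    assert np.allclose(back, [1, 2, 3], atol=1e-12)


def test_zstandardize_constant_series_errors():
    with pytest.raises(ValueError):
        zstandardize([2.0, 2.0, 2.0])


def test_zstandardize_uses_observed_cells_only():
    x = np.array([1.0, 2.0, 3.0, 100.0])
    mask = np.array([True, True, True, False])
    z, st = zstandardize(x, mask)
    assert st.mean == pytest.approx(2.0)
    assert z[:3].mean() == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# mean models
# ---------------------------------------------------------------------------

def test_harvest_mean_zero_coefficients(flat_env, zero_params):
    for t in range(1, flat_env.n_years + 1):
        assert harvest_mean("CR", t, zero_params, flat_env) == pytest.approx(0.0)


def test_harvest_mean_ar1_deviation(flat_env, zero_params):
    env = flat_env
    env.harvest[0, 0] = 0.4    # previous observed landings; trend part is 0
    zero_params.harvest["CR"] = HarvestParams(phi=0.5)
    # deviation = (0 - 0.4), so mu_2 = 0.5 * (-0.4) = -0.2
    assert harvest_mean("CR", 2, zero_params, env) == pytest.approx(-0.2)


def test_fish_mean_lagged_landings(flat_env, zero_params):
    env = flat_env
    rng = np.random.default_rng(0)
    env.harvest[:] = rng.normal(size=env.harvest.shape)   # nonzero lag values
    zero_params.fish["MN"] = FishParams(betaTR=-0.2)
    hz, _ = harvest_z(env)
    expected = -0.2 * hz[1, 2]   # TR column, previous year
    assert fish_mean("MN", 3, zero_params, env) == pytest.approx(expected, abs=1e-12)


def test_fish_mean_random_coefficients_match_hand_formula(tiny_env):
    """Duplicate-implementation oracle for the full linear predictor."""
    rng = np.random.default_rng(7)
    p = EnvParams()
    p.fish["DM"] = FishParams(beta0=rng.normal(), betaT=rng.normal(),
                              betaT2=rng.normal(), betaS=rng.normal(),
                              betaTR=rng.normal(), betaLI=rng.normal(),
                              phi=float(rng.uniform(-0.9, 0.9)), sigma=0.3)
    env = tiny_env
    tz, tz2, sstz, _ = _covariate_table(env)
    hz, _ = harvest_z(env)
    q = p.fish["DM"]

    def det(i):
        m = q.beta0 + q.betaT * tz[i] + q.betaT2 * tz2[i] + q.betaS * sstz[i]
        if i >= 1:
            m += q.betaTR * hz[i - 1, 2] + q.betaLI * hz[i - 1, 1]
        return m

    t = 3
    expected = det(t - 1) + q.phi * (det(t - 2) - env.fish[t - 2, 1])
    assert fish_mean("DM", t, p, env) == pytest.approx(expected, abs=1e-12)


def test_fish_mean_missing_lag_raises(tiny_env, zero_params):
    env = tiny_env.copy()
    env.harvest_obs[1, :] = False
    with pytest.raises(ValueError, match="impute"):
        fish_mean("MN", 3, zero_params, env)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_env_loglik_gaussian_at_mode(flat_env, zero_params):
    """Zero residuals with diagonal unit covariance: each cell contributes
    -0.5*log(2*pi)."""
    ll = env_loglik(flat_env, zero_params, complete=True)
    n_cells = flat_env.n_years * 7   # 3 harvest + 3 fish + hooks
    assert ll == pytest.approx(-0.5 * n_cells * np.log(2 * np.pi), rel=1e-12)


def test_env_loglik_matches_dense_mvn_oracle(tiny_truth, tiny_env):
    """Complete-mode density equals a naive scipy evaluation per year."""
    p = tiny_truth.env_params
    env = tiny_env
    rho = env.rho
    mu_h, mu_f, mu_k = _all_means(env, p, rho)
    expected = 0.0
    for t in range(env.n_years):
        expected += stats.multivariate_normal.logpdf(
            env.harvest[t], mu_h[t], p.cov.Sigma_harv)
        expected += stats.multivariate_normal.logpdf(
            env.fish[t], mu_f[t], p.cov.Sigma_fish)
        expected += stats.norm.logpdf(env.hooks[t], mu_k[t], p.hooks.sigma)
        expected += stats.norm.logpdf(rho[t])
    assert env_loglik(env, p, rho=rho, complete=True) == pytest.approx(expected, abs=1e-10)


def test_env_loglik_excludes_unobserved_cells(tiny_truth):
    from ternpath.simulate import gen_environment
    truth = tiny_truth
    env_full = gen_environment(truth, seed=99)
    env_masked = env_full.copy()
    env_masked.fish_obs[2, :] = False
    ll_full = env_loglik(env_full, truth.env_params, rho=env_full.rho)
    ll_masked = env_loglik(env_masked, truth.env_params, rho=env_full.rho)
    assert ll_masked != pytest.approx(ll_full)


def test_env_loglik_sigma_monotonicity(flat_env, zero_params):
    ll1 = env_loglik(flat_env, zero_params, complete=True)
    wide = EnvParams(
        harvest={j: HarvestParams(sigma=2.0) for j in ("CR", "LI", "TR")},
        fish={k: FishParams(sigma=2.0) for k in ("MN", "DM", "HR")},
        hooks=HookCoupling(sigma=2.0),
        cov=ResidualCovariance(4.0 * np.eye(3), 4.0 * np.eye(3)),
    )
    assert env_loglik(flat_env, wide, complete=True) < ll1


def test_env_loglik_series_order_invariance(tiny_truth, tiny_env):
    """Relabeling the harvest series (and permuting Sigma accordingly)
    leaves the joint density unchanged."""
    p = tiny_truth.env_params
    env = tiny_env
    perm = [2, 0, 1]
    names = ("CR", "LI", "TR")

    def clone(old):
        q = p.harvest[old]
        return HarvestParams(beta0=q.beta0, betaT=q.betaT, betaT2=q.betaT2,
                             betaS=q.betaS, phi=q.phi, sigma=q.sigma,
                             betaLL_rho=0.0)  # slot-bound coupling off

    p1 = EnvParams(harvest={nm: clone(nm) for nm in names}, fish=p.fish,
                   hooks=p.hooks, cov=p.cov)
    p2 = EnvParams(
        harvest={new: clone(names[perm[i]]) for i, new in enumerate(names)},
        fish=p.fish, hooks=p.hooks,
        cov=ResidualCovariance(p.cov.Sigma_harv[np.ix_(perm, perm)], p.cov.Sigma_fish),
    )
    env2 = env.copy()
    env2.harvest = env.harvest[:, perm]
    env2.harvest_obs = env.harvest_obs[:, perm]
    # permuting harvest columns changes the LI/TR lag columns seen by the
    # fish block, so compare the harvest contribution alone
    ll1 = _harvest_only_loglik(env, p1)
    ll2 = _harvest_only_loglik(env2, p2)
    assert ll1 == pytest.approx(ll2, abs=1e-10)


def _harvest_only_loglik(env, params):
    from ternpath.env import _all_means
    mu_h, _, _ = _all_means(env, params, None)
    return mvn_rows_loglik(env.harvest - mu_h, params.cov.Sigma_harv)


def test_non_positive_definite_covariance_rejected(flat_env, zero_params):
    bad = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    with pytest.raises(CovarianceError):
        ResidualCovariance(bad, np.eye(3))


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def test_impute_fully_observed_is_identity(tiny_truth, tiny_env):
    out = impute_missing(tiny_env, tiny_truth.env_params, rng=0)
    assert np.allclose(out.harvest, tiny_env.harvest)
    assert np.allclose(out.fish, tiny_env.fish)
    assert np.allclose(out.hooks, tiny_env.hooks)


def test_impute_degenerate_noise_gives_conditional_mean(tiny_truth):
    from ternpath.simulate import gen_environment
    truth = tiny_truth
    env = gen_environment(truth, seed=55)
    env.hooks_obs[2] = False
    p = truth.env_params
    tiny = EnvParams(harvest=p.harvest, fish=p.fish,
                     hooks=HookCoupling(beta0=p.hooks.beta0, phi=p.hooks.phi,
                                        loading=p.hooks.loading, sigma=1e-12),
                     cov=p.cov)
    a = impute_missing(env, tiny, rho=env.rho, rng=1)
    b = impute_missing(env, tiny, rho=env.rho, rng=2)
    assert a.hooks[2] == pytest.approx(b.hooks[2], abs=1e-9)  # noise-free draw


def test_env_series_csv_round_trip(tmp_path, tiny_env):
    path = tmp_path / "env.csv"
    tiny_env.write_csv(path)
    back = EnvSeries.read_csv(path)
    assert np.allclose(back.harvest, tiny_env.harvest)
    assert np.allclose(back.sst, tiny_env.sst)
    assert np.array_equal(back.harvest_obs, tiny_env.harvest_obs)
    assert np.array_equal(back.years, tiny_env.years)
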