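"""Tests for the sampler and the posterior summary calculus."""

import numpy as np
import pytest
from scipy import stats

from ternpath.inference import (
    Block,
    PosteriorDraws,
    SamplerError,
    cumulative_survival,
    f_statistic,
    hpdi,
    indirect_effect,
    rhat,
    rhat_table,
    run_sampler,
    standardize_latent_theoretic,
    survivorship_decline,
)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_f_statistic_examples():
    assert f_statistic([0.2, 0.5, 1.2]) == 1.0
    assert f_statistic([1.0, -1.0, 2.0, -2.0]) == 0.5
    assert f_statistic([1.0, 2.0, -1.0, 3.0]) == 0.75
    with pytest.raises(ValueError):
        f_statistic([1.0])


def test_hpdi_shortest_interval():
    rng = np.random.default_rng(0)
    x = rng.normal(size=40000)
    lo, hi = hpdi(x, 0.90)
    assert lo == pytest.approx(-1.645, abs=0.05)
    assert hi == pytest.approx(1.645, abs=0.05)
    # skewed distribution: the shortest interval hugs the mode
    y = rng.exponential(size=40000)
    lo, hi = hpdi(y, 0.90)
    assert lo == pytest.approx(0.0, abs=0.01)


def test_hpdi_matches_arviz():
    arviz = pytest.importorskip("arviz")
    rng = np.random.default_rng(3)
    x = rng.gamma(2.0, size=20000)
    lo, hi = hpdi(x, 0.90)
    ref = arviz.hdi(x, hdi_prob=0.90)
    assert lo == pytest.approx(ref[0], abs=0.02)
    assert hi == pytest.approx(ref[1], abs=0.02)


def test_rhat_identical_vs_shifted_chains():
    rng = np.random.default_rng(1)
    w = rng.normal(size=(4, 500))
    assert rhat(w) == pytest.approx(1.0, abs=0.02)
    shifted = w + np.array([0.0, 5.0, -5.0, 10.0])[:, None]
    assert rhat(shifted) > 3.0
    with pytest.raises(ValueError):
        rhat(w[0])


def test_rhat_matches_hand_formula():
    x = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 5.0, 6.0]])
    m, n = x.shape
    W = x.var(axis=1, ddof=1).mean()
    B = n * x.mean(axis=1).var(ddof=1)
    expected = np.sqrt(((n - 1) / n * W + B / n) / W)
    assert rhat(x) == pytest.approx(expected, rel=1e-12)


def test_standardize_identity_and_zero():
    assert standardize_latent_theoretic(2.0, "identity", 1.0, 4.0) == pytest.approx(0.5)
    for link in ("identity", "logit", "loglog"):
        assert standardize_latent_theoretic(0.0, link, 1.0, 1.0) == 0.0
    with pytest.raises(ValueError):
        standardize_latent_theoretic(1.0, "probit", 1.0, 1.0)


def test_standardize_scale_invariance():
    # rescaling x by c and beta by 1/c leaves rho unchanged
    rho1 = standardize_latent_theoretic(0.8, "logit", 2.0, 1.5)
    rho2 = standardize_latent_theoretic(0.8 / 10, "logit", 20.0, 1.5)
    assert rho1 == pytest.approx(rho2, rel=1e-12)


def test_standardize_logit_matches_latent_simulation():
    """rho from the latent-theoretic formula ~ Pearson correlation of the
    simulated logistic latent response with x."""
    rng = np.random.default_rng(11)
    n = 400000
    beta = 0.8
    x = rng.normal(size=n)
    latent = beta * x + rng.logistic(size=n)
    emp = np.corrcoef(x, latent)[0, 1]
    rho = standardize_latent_theoretic(beta, "logit", 1.0, beta * 1.0)
    assert rho == pytest.approx(emp, abs=0.01)


def test_indirect_effect_products():
    d = {"a": np.full(100, -0.5), "b": np.full(100, -0.4)}
    eff = indirect_effect(d, ["a", "b"])
    assert np.allclose(eff.product_draws, 0.2)
    d["b"] = np.zeros(100)
    assert np.allclose(indirect_effect(d, ["a", "b"]).product_draws, 0.0)
    with pytest.raises(KeyError):
        indirect_effect(d, ["a", "missing"])


def test_indirect_effect_independent_edges_center_on_zero():
    rng = np.random.default_rng(2)
    d = {"a": rng.normal(size=20000), "b": rng.normal(size=20000)}
    eff = indirect_effect(d, ["a", "b"])
    assert eff.summary.mean == pytest.approx(0.0, abs=0.03)
    assert eff.summary.f == pytest.approx(0.5, abs=0.03)


def test_cumulative_survival_examples():
    S = np.full((10, 5), 0.5)
    out = cumulative_survival(S, ages=range(1, 6))
    assert np.allclose(out["cumulative_period1"], 0.03125)
    assert survivorship_decline(0.18, 0.081) == pytest.approx(0.55)
    assert survivorship_decline(0.2, 0.2) == 0.0


def test_cumulative_survival_year_blocks():
    n_draws, n_ages, n_years = 8, 5, 6
    S = np.full((n_draws, n_ages, n_years), 0.8)
    S[:, :, 3:] = 0.4
    out = cumulative_survival(S, ages=range(1, 6),
                              year_blocks=[[0, 1, 2], [3, 4, 5]])
    assert np.allclose(out["cumulative_period1"], 0.8 ** 5)
    assert np.allclose(out["cumulative_period2"], 0.4 ** 5)
    assert np.allclose(out["decline"], 1 - 0.5 ** 5)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def test_sampler_conjugate_normal_posterior():
    """Normal likelihood with known sd + normal prior: closed-form posterior."""
    rng = np.random.default_rng(4)
    data = rng.normal(1.5, 1.0, size=50)
    prior_mu, prior_sd = 0.0, 2.0
    post_prec = 1.0 / prior_sd ** 2 + len(data)
    post_mu = (prior_mu / prior_sd ** 2 + data.sum()) / post_prec
    post_sd = 1.0 / np.sqrt(post_prec)

    terms = {
        "lik": lambda th: float(-0.5 * np.sum((data - th[0]) ** 2)),
        "prior": lambda th: float(-0.5 * ((th[0] - prior_mu) / prior_sd) ** 2),
    }
    blocks = [Block("mu", [0], ("lik", "prior"), 0.3)]
    samples, info = run_sampler(terms, blocks, np.array([0.0]), n_chains=2,
                                n_iter=4000, n_burn=1000, seed=8)
    draws = samples[:, :, 0].ravel()
    assert draws.mean() == pytest.approx(post_mu, abs=4 * post_sd / np.sqrt(200))
    assert draws.std() == pytest.approx(post_sd, rel=0.1)


def test_sampler_deterministic_under_seed():
    terms = {"lp": lambda th: float(-0.5 * th @ th)}
    blocks = [Block("all", [0, 1], ("lp",), 0.5)]
    s1, _ = run_sampler(terms, blocks, np.zeros(2), n_chains=2, n_iter=200,
                        n_burn=100, seed=13)
    s2, _ = run_sampler(terms, blocks, np.zeros(2), n_chains=2, n_iter=200,
                        n_burn=100, seed=13)
    assert np.array_equal(s1, s2)
    s3, _ = run_sampler(terms, blocks, np.zeros(2), n_chains=2, n_iter=200,
                        n_burn=100, seed=14)
    assert not np.array_equal(s1, s3)


def test_sampler_recovers_prior_with_no_data():
    """Zero-data model: draws reproduce the standard-normal prior."""
    terms = {"prior": lambda th: float(-0.5 * th[0] ** 2)}
    blocks = [Block("x", [0], ("prior",), 1.0)]
    samples, _ = run_sampler(terms, blocks, np.zeros(1), n_chains=1,
                             n_iter=8000, n_burn=1000, seed=21)
    draws = samples[0, ::8, 0]  # thin for near-independence
    stat, pval = stats.kstest(draws, "norm")
    assert pval > 0.01


def test_sampler_rejects_nonfinite_init():
    terms = {"lp": lambda th: -np.inf}
    blocks = [Block("x", [0], ("lp",), 0.1)]
    with pytest.raises(SamplerError):
        run_sampler(terms, blocks, np.zeros(1), n_chains=1, n_iter=10,
                    n_burn=10, seed=0)


def test_gibbs_block_targets_conditional():
    """A pure-Gibbs sampler on a 2d Gaussian reproduces its marginals."""
    rho = 0.8

    def gibbs_x(theta, rng):
        return np.array([rho * theta[1] + np.sqrt(1 - rho ** 2) * rng.standard_normal()])

    def gibbs_y(theta, rng):
        return np.array([rho * theta[0] + np.sqrt(1 - rho ** 2) * rng.standard_normal()])

    lp = lambda th: float(-0.5 * (th[0] ** 2 - 2 * rho * th[0] * th[1] + th[1] ** 2)
                          / (1 - rho ** 2))
    terms = {"lp": lp}
    blocks = [Block("x", [0], ("lp",), gibbs=gibbs_x),
              Block("y", [1], ("lp",), gibbs=gibbs_y)]
    samples, _ = run_sampler(terms, blocks, np.zeros(2), n_chains=1,
                             n_iter=6000, n_burn=500, seed=3)
    x = samples[0, :, 0]
    y = samples[0, :, 1]
    assert x.std() == pytest.approx(1.0, abs=0.05)
    assert np.corrcoef(x, y)[0, 1] == pytest.approx(rho, abs=0.03)


# ---------------------------------------------------------------------------
# draws container
# ---------------------------------------------------------------------------

def test_posterior_draws_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    draws = PosteriorDraws(
        draws={"a": rng.normal(size=(2, 50)), "b": rng.normal(size=(2, 50, 3))},
        seed=42, n_burn=10, meta={"note": "test"})
    draws.save(tmp_path / "d")
    back = PosteriorDraws.load(tmp_path / "d")
    assert np.allclose(back.get("a"), draws.get("a"))
    assert back.get("b").shape == (2, 50, 3)
    assert back.seed == 42


def test_rhat_table_flags_bad_parameters():
    rng = np.random.default_rng(6)
    good = rng.normal(size=(4, 300))
    bad = good + np.array([0, 3, 6, 9])[:, None]
    draws = PosteriorDraws(draws={"good": good, "bad": bad})
    out = rhat_table(draws)
    assert "bad" in out["flagged"] and "good" not in out["flagged"]
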