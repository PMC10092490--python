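"""Joint model assembly: parameters, priors, posterior terms, fitting.

Couples the environmental path model and the marginalized Barker likelihood
into one posterior.  Missing environmental cells and the hooks-coupling
factor are latent nodes (sampled each iteration, so lagged covariates and
demographic covariates are always defined); hazard, detectability, recovery
and resight year deviations are latent as well.

All sampling happens on an unconstrained scale (log for standard deviations,
logit for probabilities, atanh for correlations/AR1 coefficients) with the
appropriate Jacobian corrections.  Priors follow the source analysis where
printed -- half-Cauchy(0.16) on the recovery/resight random-effect sds,
logistic(0,1) on logit-scale means, beta(1,1) on availability, a
double-exponential lasso with exponential(0.1) scale on the hazard covariate
coefficients, and a log-gamma (exp of the intercept ~ exponential(1)) on the
hazard class intercepts; unprinted coefficient priors default to normal(0,2)
(band effects normal(0,5), raw-scale regression intercepts normal(0,100),
covariance sds half-Cauchy(1), correlations uniform over the valid region).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import env as envmod
from .barker import (
    HAZARD_COVARIATES,
    MAX_AGE,
    RECOVERY_COVARIATES,
    DemographicParams,
    DetectionParams,
    MovementParams,
    SurvivalParams,
    YearEffects,
    hazard_covariate_matrix as barker_covariates,
    marginal_loglik,
)
from .env import EnvParams, EnvSeries, FishParams, HarvestParams, HookCoupling, \
    ResidualCovariance, env_loglik
from .inference import Block, PosteriorDraws, run_sampler

_SQ = np.sqrt


# ---------------------------------------------------------------------------
# unconstrained parameter layout
# ---------------------------------------------------------------------------

def _t_id(z):
    return z


def _t_log(z):
    return np.exp(z)


def _t_logit(z):
    return 1.0 / (1.0 + np.exp(-z))


def _t_tanh(z):
    return np.tanh(z)


_TRANSFORMS = {"id": _t_id, "log": _t_log, "logit": _t_logit, "tanh": _t_tanh}


def _log_jac(kind, z, x):
    if kind == "id":
        return 0.0
    if kind == "log":
        return float(np.sum(z))
    if kind == "logit":
        return float(np.sum(np.log(x) + np.log1p(-x)))
    if kind == "tanh":
        return float(np.sum(np.log1p(-x ** 2)))
    raise ValueError(kind)


@dataclass
class Entry:
    name: str
    sl: slice
    transform: str
    init: np.ndarray


class Layout:
    """Named slices of the unconstrained parameter vector with transforms."""

    def __init__(self):
        self.entries: dict[str, Entry] = {}
        self.size = 0

    def add(self, name, n, transform="id", init=0.0):
        init = np.broadcast_to(np.asarray(init, float), (n,)).copy()
        self.entries[name] = Entry(name, slice(self.size, self.size + n),
                                   transform, init)
        self.size += n

    def idx(self, *names) -> np.ndarray:
        return np.concatenate([np.arange(self.entries[n].sl.start,
                                         self.entries[n].sl.stop) for n in names])

    def init_vector(self) -> np.ndarray:
        v = np.zeros(self.size)
        for e in self.entries.values():
            v[e.sl] = e.init
        return v

    def value(self, theta, name):
        e = self.entries[name]
        return _TRANSFORMS[e.transform](theta[e.sl])

    def log_jacobian(self, theta, name) -> float:
        e = self.entries[name]
        z = theta[e.sl]
        return _log_jac(e.transform, z, _TRANSFORMS[e.transform](z))

    def unpack_samples(self, samples) -> dict:
        """Transform raw samples (..., d) into named constrained arrays."""
        out = {}
        for e in self.entries.values():
            x = _TRANSFORMS[e.transform](samples[..., e.sl])
            out[e.name] = x[..., 0] if (e.sl.stop - e.sl.start) == 1 else x
        return out


# ---------------------------------------------------------------------------
# prior densities (constrained scale)
# ---------------------------------------------------------------------------

def _lp_normal(x, sd):
    x = np.asarray(x, float)
    return float(np.sum(-0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)))


def _lp_half_cauchy(x, tau):
    x = np.asarray(x, float)
    return float(np.sum(np.log(2.0 / (np.pi * tau)) - np.log1p((x / tau) ** 2)))


def _lp_logistic(x):
    x = np.asarray(x, float)
    return float(np.sum(-x - 2.0 * np.log1p(np.exp(-x))))


def _lp_log_gamma(x):
    # exp(x) ~ exponential(1)  =>  p(x) = exp(x - exp(x))
    x = np.asarray(x, float)
    return float(np.sum(x - np.exp(x)))


def _lp_lasso(beta, upsilon):
    # beta | upsilon ~ double-exponential(0, 1/upsilon), rows by age class
    beta = np.asarray(beta, float)
    u = np.asarray(upsilon, float)[:, None]
    return float(np.sum(np.log(u / 2.0) - u * np.abs(beta)))


def _lp_exponential(x, rate):
    x = np.asarray(x, float)
    return float(np.sum(np.log(rate) - rate * x))


def _corr3(r12, r13, r23):
    C = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    return C


def _pd_logdet(C):
    """log det via Cholesky, or None when not positive definite."""
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return None
    return 2.0 * float(np.sum(np.log(np.diag(L))))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Sampler and model-structure settings for one fit."""

    n_chains: int = 4
    n_iter: int = 2000
    n_burn: int = 2000
    thin: int = 1
    seed: int = 1
    rprime_rule: str = "half"
    min_move_age: int = 4
    #: single ages given free intercept adjustments (class references 1, 3, 5
    #: are pinned to 0); extend toward 25 for the full age-detail model
    free_adjust_ages: tuple = tuple(a for a in range(2, MAX_AGE + 1) if a not in (1, 3, 5))
    warm_start_passes: int = 2
    init_jitter: float = 0.05
    mode: str = "joint"  # "joint" | "env" | "demo"


# ---------------------------------------------------------------------------
# model builder
# ---------------------------------------------------------------------------

class JointModel:
    """Posterior terms + block structure for one dataset."""

    def __init__(self, env: EnvSeries, records=None, config: FitConfig | None = None):
        self.config = config or FitConfig()
        self.env_data = env
        self.records = records
        self.n_years = env.n_years
        self.layout = Layout()
        self._missing_index = self._collect_missing(env)
        self._recovery_cols = [HAZARD_COVARIATES.index(c) for c in RECOVERY_COVARIATES]
        self._build_layout()
        self.terms = self._build_terms()
        self.blocks = self._build_blocks()

    # -- least-squares initialization helpers -------------------------------
    def _series_ols(self, kind: str, i: int):
        """OLS fit of one series' trend+covariate mean model (no AR1 term).

        Returns (coef, resid_sd, coef_cov); used to initialize the regression
        blocks and to shape their proposals along collinear ridges.
        """
        env = self.env_data
        tz, tz2 = envmod.time_trend(env.n_years)
        sstz, _ = envmod.zstandardize(env.sst, env.sst_obs)
        cols = [np.ones(env.n_years), tz, tz2, sstz]
        if kind == "harvest":
            y, obs = env.harvest[:, i], env.harvest_obs[:, i]
        else:
            y, obs = env.fish[:, i], env.fish_obs[:, i]
            hz = np.column_stack([
                envmod.zstandardize(env.harvest[:, j], env.harvest_obs[:, j])[0]
                for j in range(3)])
            lagTR = np.concatenate([[0.0], hz[:-1, envmod._TR]])
            lagLI = np.concatenate([[0.0], hz[:-1, envmod._LI]])
            cols += [lagTR, lagLI]
            lag_ok = np.concatenate([[False], env.harvest_obs[:-1].all(axis=1)])
            obs = obs & lag_ok
        X = np.column_stack(cols)[obs]
        yv = y[obs]
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        dof = max(1, len(yv) - X.shape[1])
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X + 1e-10 * np.eye(X.shape[1]))
        # the AR1 deviation term implies lag-1 residual autocorr ~ -phi
        ac = 0.0
        if len(resid) > 5 and resid.std() > 0:
            ac = float(np.corrcoef(resid[:-1], resid[1:])[0, 1])
        phi0 = float(np.clip(-ac, -0.9, 0.9))
        sd0 = float(np.sqrt(s2 * max(0.1, 1.0 - phi0 ** 2)))
        return beta, sd0, cov, phi0

    @staticmethod
    def _ridge_chol(cov_beta, n_extra, extra_scale=0.3):
        """Proposal Cholesky: OLS coefficient shape + diagonal extras."""
        k = cov_beta.shape[0] + n_extra
        C = np.zeros((k, k))
        C[: cov_beta.shape[0], : cov_beta.shape[0]] = np.linalg.cholesky(
            cov_beta + 1e-10 * np.eye(cov_beta.shape[0]))
        for j in range(cov_beta.shape[0], k):
            C[j, j] = extra_scale
        return C * (2.38 / np.sqrt(k))

    # -- missing cells ------------------------------------------------------
    @staticmethod
    def _collect_missing(env):
        idx = []
        for t in range(env.n_years):
            for j in range(3):
                if not env.harvest_obs[t, j]:
                    idx.append(("harvest", t, j))
            for k in range(3):
                if not env.fish_obs[t, k]:
                    idx.append(("fish", t, k))
            if not env.hooks_obs[t]:
                idx.append(("hooks", t, 0))
        return idx

    # -- layout -------------------------------------------------------------
    def _build_layout(self):
        L = self.layout
        n = self.n_years
        cfg = self.config
        env = self.env_data
        fit_env = cfg.mode in ("joint", "env")
        fit_demo = cfg.mode in ("joint", "demo")

        if fit_env:
            self._ols = {}
            for ji, j in enumerate(envmod.FISHERIES):
                beta, sd, cov, phi0 = self._series_ols("harvest", ji)
                self._ols[f"harv_{j}"] = (beta, sd, cov)
                L.add(f"harv_{j}_beta", 4, "id", beta)
                L.add(f"harv_{j}_phi", 1, "tanh", np.arctanh(phi0))
                L.add(f"harv_{j}_sigma", 1, "log", np.log(max(sd, 0.02)))
            L.add("betaLL_rho", 1, "id", 0.0)
            for ki, k in enumerate(envmod.SPECIES):
                beta, sd, cov, phi0 = self._series_ols("fish", ki)
                self._ols[f"fish_{k}"] = (beta, sd, cov)
                L.add(f"fish_{k}_beta", 6, "id", beta)
                L.add(f"fish_{k}_phi", 1, "tanh", np.arctanh(phi0))
                L.add(f"fish_{k}_sigma", 1, "log", np.log(max(sd, 0.02)))
            yh = env.hooks[env.hooks_obs]
            L.add("hooks_beta0", 1, "id", float(np.mean(yh)))
            L.add("hooks_phi", 1, "tanh", 0.0)
            # positive loading resolves the latent factor's sign ambiguity
            L.add("hooks_loading", 1, "log", np.log(0.2))
            L.add("hooks_sigma", 1, "log", np.log(max(np.std(yh), 0.05)))
            L.add("corr_harv", 3, "tanh", 0.0)
            L.add("corr_fish", 3, "tanh", 0.0)
            L.add("rho", n, "id", 0.0)
            if self._missing_index:
                init = [self._naive_cell_guess(kind, t, j)
                        for kind, t, j in self._missing_index]
                L.add("env_missing", len(self._missing_index), "id", init)

        if fit_demo:
            # the yearly demographic levels are parameterized *absolutely*
            # (v_* latents carry the likelihood; intercepts, covariate slopes
            # and random-effect scales act at the prior level only), which
            # removes the translation ridges between means and deviations
            L.add("haz_beta0", 3, "id", [0.2, -1.0, -1.3])
            if cfg.free_adjust_ages:
                L.add("haz_beta_age", len(cfg.free_adjust_ages), "id", 0.0)
            L.add("haz_beta_x", 3 * len(HAZARD_COVARIATES), "id", 0.0)
            L.add("haz_upsilon", 3, "log", 0.0)
            L.add("haz_sd", 3, "log", np.log(0.2))
            L.add("haz_corr", 3, "tanh", 0.0)
            # parameter-expanded yearly log-hazards: v = level + deviation.
            # The redundant class-level coordinate lets the overall hazard
            # level move jointly with fidelity/availability in one adaptive
            # block, which is the slow ridge of this posterior.
            L.add("haz_level", 3, "id", [0.2, -1.0, -1.3])
            L.add("v_haz", 3 * n, "id", 0.0)
            L.add("F", 1, "logit", 3.0)
            L.add("psi", 1, "logit", 3.0)
            L.add("alpha", 5, "logit", [-3.0, -2.0, -1.0, 0.0, 1.0])
            L.add("p_mean", 2, "id", -6.0)
            L.add("p_sd", 2, "log", np.log(1.0))
            L.add("p_corr", 1, "tanh", 0.0)
            L.add("v_p", 2 * n, "id", -6.0)
            L.add("p_band", 2, "id", 0.0)
            L.add("r_intercept", 1, "id", -4.0)
            L.add("r_beta_x", len(RECOVERY_COVARIATES), "id", 0.0)
            L.add("r_beta_NC", 1, "id", 0.0)
            L.add("r_band", 2, "id", 0.0)
            L.add("sigma_r", 1, "log", np.log(0.3))
            L.add("v_r", n, "id", -4.0)
            L.add("R_mean", 1, "id", -6.0)
            L.add("R_beta_NC", 1, "id", 0.0)
            L.add("R_band", 2, "id", 0.0)
            L.add("sigma_R", 1, "log", np.log(1.0))
            L.add("v_R", n, "id", -6.0)

    def _naive_cell_guess(self, kind, t, j):
        """Initial value for a latent cell: the OLS trend prediction for its
        year (a series mean would put an off-trend kink at the gap)."""
        env = self.env_data
        if kind == "hooks":
            return float(np.mean(env.hooks[env.hooks_obs]))
        tz, tz2 = envmod.time_trend(env.n_years)
        sstz, _ = envmod.zstandardize(env.sst, env.sst_obs)
        row = [1.0, tz[t], tz2[t], sstz[t]]
        if kind == "harvest":
            beta = self._ols[f"harv_{envmod.FISHERIES[j]}"][0]
        else:
            lag = [0.0, 0.0]
            if t >= 1 and env.harvest_obs[t - 1].all():
                hz = np.column_stack([
                    envmod.zstandardize(env.harvest[:, c], env.harvest_obs[:, c])[0]
                    for c in range(3)])
                lag = [hz[t - 1, envmod._TR], hz[t - 1, envmod._LI]]
            row += lag
            beta = self._ols[f"fish_{envmod.SPECIES[j]}"][0]
        return float(np.asarray(row) @ beta)

    # -- parameter extraction ----------------------------------------------
    def env_params(self, theta) -> tuple[EnvParams, np.ndarray]:
        L = self.layout
        harvest = {}
        for j in envmod.FISHERIES:
            b = L.value(theta, f"harv_{j}_beta")
            harvest[j] = HarvestParams(
                beta0=b[0], betaT=b[1], betaT2=b[2], betaS=b[3],
                phi=float(L.value(theta, f"harv_{j}_phi")[0]),
                sigma=float(L.value(theta, f"harv_{j}_sigma")[0]),
                betaLL_rho=float(L.value(theta, "betaLL_rho")[0]) if j == "LI" else 0.0,
            )
        fish = {}
        for k in envmod.SPECIES:
            b = L.value(theta, f"fish_{k}_beta")
            fish[k] = FishParams(
                beta0=b[0], betaT=b[1], betaT2=b[2], betaS=b[3],
                betaTR=b[4], betaLI=b[5],
                phi=float(L.value(theta, f"fish_{k}_phi")[0]),
                sigma=float(L.value(theta, f"fish_{k}_sigma")[0]),
            )
        hooks = HookCoupling(
            beta0=float(L.value(theta, "hooks_beta0")[0]),
            phi=float(L.value(theta, "hooks_phi")[0]),
            loading=float(L.value(theta, "hooks_loading")[0]),
            sigma=float(L.value(theta, "hooks_sigma")[0]),
        )
        ch = L.value(theta, "corr_harv")
        cf = L.value(theta, "corr_fish")
        sd_h = np.array([harvest[j].sigma for j in envmod.FISHERIES])
        sd_f = np.array([fish[k].sigma for k in envmod.SPECIES])
        Ch = _corr3(*ch)
        Cf = _corr3(*cf)
        if _pd_logdet(Ch) is None or _pd_logdet(Cf) is None:
            raise FloatingPointError("correlation matrix outside valid region")
        cov = ResidualCovariance.unchecked(np.outer(sd_h, sd_h) * Ch,
                                           np.outer(sd_f, sd_f) * Cf)
        params = EnvParams(harvest=harvest, fish=fish, hooks=hooks, cov=cov)
        rho = L.value(theta, "rho")
        return params, rho

    def completed_env(self, theta) -> EnvSeries:
        """EnvSeries with latent cells replaced by their current values.

        Cached on the latent-cell values: most block updates leave them
        untouched, so the same completed copy (and its internal covariate
        caches) is reused across likelihood evaluations.
        """
        env = self.env_data
        if not self._missing_index or "env_missing" not in self.layout.entries:
            return env
        vals = self.layout.value(theta, "env_missing")
        key = vals.tobytes()
        if getattr(self, "_env_cache_key", None) == key:
            return self._env_cache
        out = env.copy()
        for (kind, t, j), v in zip(self._missing_index, vals):
            if kind == "harvest":
                out.harvest[t, j] = v
            elif kind == "fish":
                out.fish[t, j] = v
            else:
                out.hooks[t] = v
        self._env_cache_key = key
        self._env_cache = out
        return out

    def demo_params(self, theta) -> tuple[DemographicParams, YearEffects]:
        """Likelihood-side parameter assembly.

        The absolute yearly latents ``v_*`` are passed through the
        ``YearEffects`` slots while the corresponding means/slopes are zeroed
        in the parameter blocks, so ``realized_rates`` composes exactly the
        intended per-year rates; the regression structure acts on the
        latents at the prior level only (see the ``pr_*`` terms).
        """
        L = self.layout
        cfg = self.config
        n = self.n_years
        beta_age = np.zeros(MAX_AGE)
        if cfg.free_adjust_ages:
            vals = L.value(theta, "haz_beta_age")
            for a, v in zip(cfg.free_adjust_ages, vals):
                beta_age[a - 1] = v
        survival = SurvivalParams(
            beta0_A=np.zeros(3),
            beta_age=beta_age,
            beta_x_A=np.zeros((3, len(HAZARD_COVARIATES))),
            Sigma_A=np.eye(3),
        )
        movement = MovementParams(F=float(L.value(theta, "F")[0]),
                                  psi=float(L.value(theta, "psi")[0]),
                                  min_move_age=cfg.min_move_age)
        detection = DetectionParams(
            alpha_hat=L.value(theta, "alpha"),
            p_mean=np.zeros(2),
            Sigma_p=np.eye(2),
            beta_p_band=L.value(theta, "p_band"),
            r_intercept=0.0,
            r_beta_x=np.zeros(len(RECOVERY_COVARIATES)),
            r_beta_NC=float(L.value(theta, "r_beta_NC")[0]),
            r_beta_band=L.value(theta, "r_band"),
            sigma_r=1.0,
            R_mean=0.0,
            R_beta_NC=float(L.value(theta, "R_beta_NC")[0]),
            R_beta_band=L.value(theta, "R_band"),
            sigma_R=1.0,
            rprime_rule=cfg.rprime_rule,
        )
        effects = YearEffects(
            hazard=(L.value(theta, "haz_level")[None, :]
                    + L.value(theta, "v_haz").reshape(n, 3)),
            u_r=L.value(theta, "v_r"),
            u_R=L.value(theta, "v_R"),
            u_p=L.value(theta, "v_p").reshape(n, 2),
        )
        return DemographicParams(survival=survival, movement=movement,
                                 detection=detection), effects

    # -- posterior terms ----------------------------------------------------
    def _build_terms(self):
        """Posterior terms, split so a block only re-evaluates what it moves.

        The likelihood terms are ``env`` (which also carries the latent-cell
        and coupling-factor densities) and ``demo``; the prior is split into
        per-component ``pr_*`` terms.  The log-posterior is the sum of all
        terms.
        """
        cfg = self.config
        L = self.layout
        terms = {}

        if cfg.mode in ("joint", "env"):
            def env_term(theta):
                try:
                    params, rho = self.env_params(theta)
                except (FloatingPointError, ValueError):
                    return -np.inf
                env = self.completed_env(theta)
                return env_loglik(env, params, rho=rho, complete=True)

            terms["env"] = env_term

            def make_harv_prior(j):
                def pr(theta):
                    b = L.value(theta, f"harv_{j}_beta")
                    lp = _lp_normal(b[0], 100.0) + _lp_normal(b[1:], 2.0)
                    lp += L.log_jacobian(theta, f"harv_{j}_phi")  # uniform(-1,1)
                    s = L.value(theta, f"harv_{j}_sigma")
                    lp += _lp_half_cauchy(s, 1.0) + L.log_jacobian(theta, f"harv_{j}_sigma")
                    if j == "LI":
                        lp += _lp_normal(L.value(theta, "betaLL_rho"), 2.0)
                    return lp
                return pr

            def make_fish_prior(k):
                def pr(theta):
                    b = L.value(theta, f"fish_{k}_beta")
                    lp = _lp_normal(b[0], 100.0) + _lp_normal(b[1:], 2.0)
                    lp += L.log_jacobian(theta, f"fish_{k}_phi")
                    s = L.value(theta, f"fish_{k}_sigma")
                    lp += _lp_half_cauchy(s, 1.0) + L.log_jacobian(theta, f"fish_{k}_sigma")
                    return lp
                return pr

            for j in envmod.FISHERIES:
                terms[f"pr_harv_{j}"] = make_harv_prior(j)
            for k in envmod.SPECIES:
                terms[f"pr_fish_{k}"] = make_fish_prior(k)

            def pr_hooks(theta):
                lp = _lp_normal(L.value(theta, "hooks_beta0"), 100.0)
                lp += L.log_jacobian(theta, "hooks_phi")
                lp += _lp_normal(L.value(theta, "hooks_loading"), 2.0)  # half-normal
                lp += L.log_jacobian(theta, "hooks_loading")
                lp += _lp_half_cauchy(L.value(theta, "hooks_sigma"), 1.0)
                lp += L.log_jacobian(theta, "hooks_sigma")
                return lp

            def pr_corr(theta):
                lp = 0.0
                for nm in ("corr_harv", "corr_fish"):
                    C = _corr3(*L.value(theta, nm))
                    if _pd_logdet(C) is None:
                        return -np.inf
                    lp += L.log_jacobian(theta, nm)  # flat over the valid region
                return lp

            terms["pr_hooks"] = pr_hooks
            terms["pr_corr"] = pr_corr
            # rho prior and missing-cell densities live in the env term

        if cfg.mode in ("joint", "demo"):
            n = self.n_years

            from .barker import _pack_records

            packed = _pack_records(self.records, self.env_data.years)

            def demo_term(theta):
                try:
                    params, effects = self.demo_params(theta)
                except (FloatingPointError, ValueError):
                    return -np.inf
                env = self.completed_env(theta) if cfg.mode == "joint" else self.env_data
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    return marginal_loglik(self.records, params, env, effects,
                                           packed=packed)

            terms["demo"] = demo_term

            def pr_haz_main(theta):
                lp = _lp_log_gamma(L.value(theta, "haz_beta0"))
                if cfg.free_adjust_ages:
                    lp += _lp_normal(L.value(theta, "haz_beta_age"), 2.0)
                return lp

            def pr_haz_x(theta):
                ups = L.value(theta, "haz_upsilon")
                lp = _lp_lasso(L.value(theta, "haz_beta_x").reshape(3, -1), ups)
                lp += _lp_exponential(ups, 0.1) + L.log_jacobian(theta, "haz_upsilon")
                return lp

            def pr_v_haz(theta):
                # v_{A,t} ~ MVN(beta0_A + x_t' beta_A, Sigma_A): the hazard
                # regression acts on the yearly latent levels
                sd_A = L.value(theta, "haz_sd")
                CA = _corr3(*L.value(theta, "haz_corr"))
                if _pd_logdet(CA) is None:
                    return -np.inf
                lp = _lp_half_cauchy(sd_A, 1.0) + L.log_jacobian(theta, "haz_sd")
                lp += L.log_jacobian(theta, "haz_corr")
                X = barker_covariates(self.completed_env(theta))
                mean = (L.value(theta, "haz_beta0")[None, :]
                        + X @ L.value(theta, "haz_beta_x").reshape(3, -1).T)
                v = (L.value(theta, "haz_level")[None, :]
                     + L.value(theta, "v_haz").reshape(n, 3))
                try:
                    lp += envmod.mvn_rows_loglik(v - mean,
                                                 np.outer(sd_A, sd_A) * CA)
                except np.linalg.LinAlgError:
                    return -np.inf
                # proper prior on the redundant level coordinate
                lp += _lp_normal(L.value(theta, "haz_level"), 10.0)
                return lp

            def pr_move_alpha(theta):
                return (L.log_jacobian(theta, "F") + L.log_jacobian(theta, "psi")
                        + L.log_jacobian(theta, "alpha"))  # beta(1,1) / uniform

            def pr_det_p(theta):
                return (_lp_logistic(L.value(theta, "p_mean"))
                        + _lp_normal(L.value(theta, "p_band"), 5.0))

            def pr_v_p(theta):
                p_sd = L.value(theta, "p_sd")
                lp = _lp_half_cauchy(p_sd, 1.0) + L.log_jacobian(theta, "p_sd")
                lp += L.log_jacobian(theta, "p_corr")
                pc = float(L.value(theta, "p_corr")[0])
                Sp = np.array([[p_sd[0] ** 2, pc * p_sd[0] * p_sd[1]],
                               [pc * p_sd[0] * p_sd[1], p_sd[1] ** 2]])
                resid = L.value(theta, "v_p").reshape(n, 2) - L.value(theta, "p_mean")[None, :]
                try:
                    lp += envmod.mvn_rows_loglik(resid, Sp)
                except np.linalg.LinAlgError:
                    return -np.inf
                return lp

            def pr_r(theta):
                return (_lp_normal(L.value(theta, "r_intercept"), 5.0)
                        + _lp_normal(L.value(theta, "r_beta_x"), 2.0)
                        + _lp_normal(L.value(theta, "r_beta_NC"), 2.0)
                        + _lp_normal(L.value(theta, "r_band"), 5.0))

            def pr_v_r(theta):
                s_r = float(L.value(theta, "sigma_r")[0])
                lp = _lp_half_cauchy(s_r, 0.16) + L.log_jacobian(theta, "sigma_r")
                X = barker_covariates(self.completed_env(theta))
                Xr = X[:, self._recovery_cols]
                mean = (float(L.value(theta, "r_intercept")[0])
                        + Xr @ L.value(theta, "r_beta_x"))
                lp += _lp_normal(L.value(theta, "v_r") - mean, s_r)
                return lp

            def pr_R(theta):
                return (_lp_logistic(L.value(theta, "R_mean"))
                        + _lp_normal(L.value(theta, "R_beta_NC"), 2.0)
                        + _lp_normal(L.value(theta, "R_band"), 5.0))

            def pr_v_R(theta):
                s_R = float(L.value(theta, "sigma_R")[0])
                lp = _lp_half_cauchy(s_R, 0.16) + L.log_jacobian(theta, "sigma_R")
                lp += _lp_normal(L.value(theta, "v_R")
                                 - float(L.value(theta, "R_mean")[0]), s_R)
                return lp

            terms.update(pr_haz_main=pr_haz_main, pr_haz_x=pr_haz_x,
                         pr_v_haz=pr_v_haz, pr_move_alpha=pr_move_alpha,
                         pr_det_p=pr_det_p, pr_v_p=pr_v_p, pr_r=pr_r,
                         pr_v_r=pr_v_r, pr_R=pr_R, pr_v_R=pr_v_R)
        return terms

    def log_posterior(self, theta) -> float:
        """Sum of all posterior terms (handy for tests and debugging)."""
        return float(sum(f(theta) for f in self.terms.values()))

    # -- exact Gibbs draws for conditionally Gaussian coefficients ----------
    def _gibbs_env_beta(self, kind: str, si: int):
        """Exact Gaussian full-conditional draw of one series' mean
        coefficients.

        With phi, the residual covariance, the latent factor and the latent
        cells held fixed, the AR1 mean model is linear in the coefficients:
        ``mu_t = (x_t + phi * x_{t-1}) @ beta - phi * y_{t-1}``, and the
        within-year residual of this series conditional on its two siblings
        is univariate normal -- so the coefficient posterior is Gaussian.
        Direct draws traverse the trend/SST/lagged-landings collinearity
        ridge that a random walk crosses only slowly.
        """
        n = self.n_years

        def draw(theta, rng):
            params, rho = self.env_params(theta)
            env = self.completed_env(theta)
            tz, tz2, sstz, _ = envmod._covariate_table(env)
            ones = np.ones(n)
            if kind == "harvest":
                x = np.column_stack([ones, tz, tz2, sstz])
                if si == envmod._LI:
                    x = np.column_stack([x, rho])
                y = env.harvest[:, si]
                Y = env.harvest
                Sigma = params.cov.Sigma_harv
                phi = params.harvest[envmod.FISHERIES[si]].phi
                mu_all = envmod._all_means(env, params, rho)[0]
            else:
                hz, _ = envmod.harvest_z(env)
                lagTR = np.concatenate([[0.0], hz[:-1, envmod._TR]])
                lagLI = np.concatenate([[0.0], hz[:-1, envmod._LI]])
                x = np.column_stack([ones, tz, tz2, sstz, lagTR, lagLI])
                y = env.fish[:, si]
                Y = env.fish
                Sigma = params.cov.Sigma_fish
                phi = params.fish[envmod.SPECIES[si]].phi
                mu_all = envmod._all_means(env, params, rho)[1]

            # AR1-folded design and response
            Xt = x.copy()
            Xt[1:] += phi * x[:-1]
            yt = y.copy()
            yt[1:] += phi * y[:-1]
            # condition on the sibling residuals through Sigma
            others = [m for m in range(3) if m != si]
            e_oth = (Y - mu_all)[:, others]
            S_oo = Sigma[np.ix_(others, others)]
            S_jo = Sigma[si, others]
            w = np.linalg.solve(S_oo, S_jo)
            shift = e_oth @ w
            cvar = float(Sigma[si, si] - S_jo @ w)
            cvar = max(cvar, 1e-12)
            k = Xt.shape[1]
            prior_prec = np.full(k, 0.25)   # normal(0, 2) coefficients
            prior_prec[0] = 1.0 / 100.0 ** 2
            A = Xt.T @ Xt / cvar + np.diag(prior_prec)
            b = Xt.T @ (yt - shift) / cvar
            La = np.linalg.cholesky(A)
            mean = np.linalg.solve(La.T, np.linalg.solve(La, b))
            z = np.linalg.solve(La.T, rng.standard_normal(k))
            return mean + z

        return draw

    # -- block structure ----------------------------------------------------
    def _build_blocks(self):
        cfg = self.config
        L = self.layout
        blocks = []

        if cfg.mode in ("joint", "env"):
            for ji, j in enumerate(envmod.FISHERIES):
                names = [f"harv_{j}_beta"] + (["betaLL_rho"] if j == "LI" else [])
                t = ("env", f"pr_harv_{j}")
                blocks.append(Block(f"env_harv_{j}_beta", L.idx(*names), t,
                                    gibbs=self._gibbs_env_beta("harvest", ji)))
                blocks.append(Block(f"env_harv_{j}_ar",
                                    L.idx(f"harv_{j}_phi", f"harv_{j}_sigma"),
                                    t, 0.15))
            for ki, k in enumerate(envmod.SPECIES):
                t = ("env", f"pr_fish_{k}")
                blocks.append(Block(f"env_fish_{k}_beta", L.idx(f"fish_{k}_beta"),
                                    t, gibbs=self._gibbs_env_beta("fish", ki)))
                blocks.append(Block(f"env_fish_{k}_ar",
                                    L.idx(f"fish_{k}_phi", f"fish_{k}_sigma"),
                                    t, 0.15))
            blocks.append(Block("env_hooks",
                                L.idx("hooks_beta0", "hooks_phi", "hooks_loading",
                                      "hooks_sigma"), ("env", "pr_hooks"), 0.05))
            blocks.append(Block("env_corr", L.idx("corr_harv", "corr_fish"),
                                ("env", "pr_corr"), 0.1))
            blocks.append(Block("env_rho", L.idx("rho"), ("env",), 0.2))
            if "env_missing" in L.entries:
                # per-gap sub-blocks: the latent cells are high-leverage for
                # the trends, and a single wide random-walk block mixes slowly
                miss_terms = (("env", "demo", "pr_v_haz", "pr_v_r")
                              if cfg.mode == "joint" else ("env",))
                base = L.entries["env_missing"].sl.start
                groups: dict = {}
                for off, (kind, t_, j) in enumerate(self._missing_index):
                    groups.setdefault((kind, t_ // 10), []).append(base + off)
                for gi, idx in enumerate(groups.values()):
                    blocks.append(Block(f"env_missing_{gi}", np.asarray(idx),
                                        miss_terms, 0.1))

        if cfg.mode in ("joint", "demo"):
            n = self.n_years
            # likelihood-side blocks (each pays one demo evaluation)
            if cfg.free_adjust_ages:
                blocks.append(Block("haz_age_adjust", L.idx("haz_beta_age"),
                                    ("demo", "pr_haz_main"), 0.05))
            vh = L.idx("v_haz").reshape(n, 3)
            ones = np.ones((n, 1))
            lev_idx = L.idx("haz_level")
            for a in range(3):
                # deviations + the class level together: the adapted block
                # covariance learns their coupling
                blocks.append(Block(f"v_haz_{a}",
                                    np.concatenate([vh[:, a], lev_idx[a:a + 1]]),
                                    ("demo", "pr_v_haz"), 0.1))
            # the joint hazard-level / fidelity / availability block walks
            # the posterior's dominant tradeoff ridge with a full adapted
            # covariance; single-coordinate level moves diffuse faster along
            # each class level on their own
            blocks.append(Block("tradeoff",
                                L.idx("haz_level", "F", "psi", "alpha"),
                                ("demo", "pr_v_haz", "pr_move_alpha"), 0.05))
            lev = L.idx("haz_level")
            for a in range(3):
                blocks.append(Block(f"haz_level_{a}", lev[a:a + 1],
                                    ("demo", "pr_v_haz"), 0.05))
            blocks.append(Block("move_alpha", L.idx("F", "psi", "alpha"),
                                ("demo", "pr_move_alpha"), 0.1))
            blocks.append(Block("p_band", L.idx("p_band"), ("demo", "pr_det_p"), 0.2))
            blocks.append(Block("r_effects", L.idx("r_beta_NC", "r_band"),
                                ("demo", "pr_r"), 0.1))
            blocks.append(Block("R_effects", L.idx("R_beta_NC", "R_band"),
                                ("demo", "pr_R"), 0.1))
            blocks.append(Block("v_p", L.idx("v_p"), ("demo", "pr_v_p"), 0.2))
            blocks.append(Block("v_r", L.idx("v_r"), ("demo", "pr_v_r"), 0.1))
            blocks.append(Block("shift_v_r", L.idx("v_r"),
                                ("demo", "pr_v_r"), 0.05, move=ones))
            blocks.append(Block("v_R", L.idx("v_R"), ("demo", "pr_v_R"), 0.2))
            blocks.append(Block("shift_v_R", L.idx("v_R"),
                                ("demo", "pr_v_R"), 0.1, move=ones))
            # prior-level regression blocks (cheap: no demo evaluation)
            for a in range(3):
                bx = L.idx("haz_beta_x").reshape(3, -1)
                blocks.append(Block(
                    f"haz_reg_{a}",
                    np.concatenate([[L.idx("haz_beta0")[a]], bx[a]]),
                    ("pr_haz_main", "pr_haz_x", "pr_v_haz"), 0.1))
            blocks.append(Block("haz_hyper", L.idx("haz_upsilon", "haz_sd", "haz_corr"),
                                ("pr_haz_x", "pr_v_haz"), 0.1))
            blocks.append(Block("p_mean", L.idx("p_mean"),
                                ("pr_det_p", "pr_v_p"), 0.2))
            blocks.append(Block("r_reg", L.idx("r_intercept", "r_beta_x"),
                                ("pr_r", "pr_v_r"), 0.1))
            blocks.append(Block("R_mean", L.idx("R_mean"),
                                ("pr_R", "pr_v_R"), 0.2))
            blocks.append(Block("det_sds", L.idx("p_sd", "p_corr", "sigma_r",
                                                 "sigma_R"),
                                ("pr_v_p", "pr_v_r", "pr_v_R"), 0.1))
        return blocks

    # -- packing known parameters (recovery studies, local-mode checks) -----
    def pack_truth(self, truth, study=None) -> np.ndarray:
        """Map a generating parameter set (and, when given, a simulated
        study's realized latents) onto the unconstrained vector.

        Useful for local-mode sanity checks and for initializing desk-scale
        recovery fits at the generating values.
        """
        L = self.layout
        theta = L.init_vector()

        def setv(name, vals, transform="id"):
            if name not in L.entries:
                return
            v = np.atleast_1d(np.asarray(vals, float))
            if transform == "log":
                v = np.log(v)
            elif transform == "logit":
                v = np.log(v / (1.0 - v))
            elif transform == "tanh":
                v = np.arctanh(v)
            theta[L.entries[name].sl] = v

        cfg = self.config
        if cfg.mode in ("joint", "env"):
            ep = truth.env_params
            for j in envmod.FISHERIES:
                q = ep.harvest[j]
                setv(f"harv_{j}_beta", [q.beta0, q.betaT, q.betaT2, q.betaS])
                setv(f"harv_{j}_phi", q.phi, "tanh")
                setv(f"harv_{j}_sigma", q.sigma, "log")
            setv("betaLL_rho", ep.harvest["LI"].betaLL_rho)
            for k in envmod.SPECIES:
                q = ep.fish[k]
                setv(f"fish_{k}_beta", [q.beta0, q.betaT, q.betaT2, q.betaS,
                                        q.betaTR, q.betaLI])
                setv(f"fish_{k}_phi", q.phi, "tanh")
                setv(f"fish_{k}_sigma", q.sigma, "log")
            setv("hooks_beta0", ep.hooks.beta0)
            setv("hooks_phi", ep.hooks.phi, "tanh")
            setv("hooks_loading", max(ep.hooks.loading, 1e-6), "log")
            setv("hooks_sigma", ep.hooks.sigma, "log")
            for nm, S in (("corr_harv", ep.cov.Sigma_harv),
                          ("corr_fish", ep.cov.Sigma_fish)):
                sd = np.sqrt(np.diag(S))
                C = S / np.outer(sd, sd)
                setv(nm, np.clip([C[0, 1], C[0, 2], C[1, 2]], -0.999, 0.999), "tanh")
            env = study.env if study is not None else self.env_data
            if env.rho is not None:
                setv("rho", env.rho)
            if self._missing_index and "env_missing" in L.entries:
                vals = []
                for kind, t, j in self._missing_index:
                    if kind == "harvest":
                        vals.append(env.harvest[t, j])
                    elif kind == "fish":
                        vals.append(env.fish[t, j])
                    else:
                        vals.append(env.hooks[t])
                setv("env_missing", vals)

        if cfg.mode in ("joint", "demo"):
            sv = truth.demo_params.survival
            dt = truth.demo_params.detection
            mv = truth.demo_params.movement
            setv("haz_beta0", sv.beta0_A)
            if cfg.free_adjust_ages:
                setv("haz_beta_age", sv.beta_age[[a - 1 for a in cfg.free_adjust_ages]])
            setv("haz_beta_x", sv.beta_x_A.ravel())
            sd = np.sqrt(np.diag(sv.Sigma_A))
            CA = sv.Sigma_A / np.outer(sd, sd)
            setv("haz_sd", sd, "log")
            setv("haz_corr", np.clip([CA[0, 1], CA[0, 2], CA[1, 2]], -0.999, 0.999),
                 "tanh")
            setv("F", mv.F, "logit")
            setv("psi", mv.psi, "logit")
            setv("alpha", np.clip(dt.alpha_hat, 1e-6, 1 - 1e-6), "logit")
            setv("p_mean", dt.p_mean)
            psd = np.sqrt(np.diag(dt.Sigma_p))
            setv("p_sd", psd, "log")
            setv("p_corr", np.clip(dt.Sigma_p[0, 1] / (psd[0] * psd[1]),
                                   -0.999, 0.999), "tanh")
            setv("p_band", dt.beta_p_band)
            setv("r_intercept", dt.r_intercept)
            setv("r_beta_x", dt.r_beta_x)
            setv("r_beta_NC", dt.r_beta_NC)
            setv("r_band", dt.r_beta_band)
            setv("sigma_r", dt.sigma_r, "log")
            setv("R_mean", dt.R_mean)
            setv("R_beta_NC", dt.R_beta_NC)
            setv("R_band", dt.R_beta_band)
            setv("sigma_R", dt.sigma_R, "log")
            # yearly latent levels = regression mean + realized deviation
            env = self.completed_env(theta)
            X = barker_covariates(env)
            eff = (study.effects if study is not None
                   else YearEffects.zeros(self.n_years))
            setv("haz_level", sv.beta0_A)
            setv("v_haz", (X @ sv.beta_x_A.T + eff.hazard).ravel())
            setv("v_p", (dt.p_mean[None, :] + eff.u_p).ravel())
            Xr = X[:, self._recovery_cols]
            setv("v_r", dt.r_intercept + Xr @ dt.r_beta_x + eff.u_r)
            setv("v_R", dt.R_mean + eff.u_R)
        return theta

    # -- warm start ---------------------------------------------------------
    def warm_start(self, theta=None, n_passes=None, maxiter=60):
        """Cheap block-relaxation toward the posterior mode before sampling.

        Cycles over the structural blocks (latent year-deviation blocks are
        left alone) maximizing the affected terms with derivative-free
        Powell steps.  Purely an initialization device -- inference comes
        from the sampler.
        """
        theta = self.layout.init_vector() if theta is None else theta.copy()
        n_passes = self.config.warm_start_passes if n_passes is None else n_passes
        # hyper-sd blocks stay at their inits (optimizing scales against
        # near-prior latents collapses them); the latent coupling factor is
        # left at its prior mean
        skip = {"env_rho", "haz_hyper", "det_sds"}
        for _ in range(n_passes):
            for b in self.blocks:
                if b.name in skip:
                    continue

                def neg(x, b=b, theta=theta):
                    full = theta.copy()
                    full[b.idx] = x
                    tot = 0.0
                    for t in b.terms:
                        v = self.terms[t](full)
                        if not np.isfinite(v):
                            return 1e12
                        tot += v
                    return -tot

                d = b.idx.size
                maxfev = 40 * d if d <= 10 else 600 + 8 * d
                res = optimize.minimize(neg, theta[b.idx], method="Powell",
                                        options={"maxiter": maxiter,
                                                 "maxfev": maxfev,
                                                 "xtol": 1e-3, "ftol": 1e-4})
                theta[b.idx] = res.x
        return theta

    # -- fit ----------------------------------------------------------------
    def fit(self, seed=None, init=None) -> PosteriorDraws:
        """Warm-start (unless ``init`` is given) and sample the posterior."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        theta0 = self.warm_start() if init is None else np.asarray(init, float)
        samples, info = run_sampler(
            self.terms, self.blocks, theta0, n_chains=cfg.n_chains,
            n_iter=cfg.n_iter, n_burn=cfg.n_burn, seed=seed, thin=cfg.thin,
            init_jitter=cfg.init_jitter)
        named = self.layout.unpack_samples(samples)
        draws = PosteriorDraws(
            draws={k: np.asarray(v) for k, v in named.items()},
            seed=seed, n_burn=cfg.n_burn,
            meta={"acceptance": {k: list(v) for k, v in info["acceptance"].items()},
                  "mode": cfg.mode},
        )
        return draws
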