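"""Environmental path sub-model.

Annual ocean/fishery time series are tied together in a small recursive
regression network:

* three log-scale landings series -- Caribbean artisanal (CR), Atlantic
  long-line/net (LI) and Atlantic trawl (TR) -- each regressed on a quadratic
  time trend, the current winter sea-surface temperature (SST) and a
  first-order autoregressive (AR1) term on the previous year's deviation of
  the observed landings from their trend expectation;
* three log-scale age-1 fish production indices -- Atlantic menhaden (MN),
  red drum (DM) and herring (HR) -- regressed on trend, SST, the AR1
  deviation term and the *lagged* trawl and long-line landings;
* a log-scale long-line effort series (hooks deployed) coupled to the LI
  landings through a shared latent standard-normal yearly factor ``rho_t``.

Within-year residuals of the landings triple and of the production triple are
multivariate normal with free covariance matrices (sd vector + correlation
matrix decomposition).  SST is exogenous throughout: it appears only on the
right-hand side.

The AR1 deviation is taken against the trend + covariate part of the mean
(not against the full recursive mean), so the detrended residuals of each
series follow a genuine AR(1) with stationary variance ``sigma^2/(1-phi^2)``.

Missing years (the study's landings after 2015, production outside
1965--2015, hooks before 1993 -- configurable ranges here) are latent: they
are predicted from the fitted model, and during joint fitting they are
sampled as unknowns so that lagged covariates are always defined.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

FISHERIES = ("CR", "LI", "TR")
SPECIES = ("MN", "DM", "HR")
#: tidy-CSV variable names, in canonical column order
ENV_VARIABLES = ("sst",) + tuple(f"harvest_{j}" for j in FISHERIES) + tuple(
    f"fish_{k}" for k in SPECIES
) + ("hooks",)

_LI = FISHERIES.index("LI")
_TR = FISHERIES.index("TR")


class CovarianceError(ValueError):
    """Raised when a residual covariance matrix is not positive definite."""


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Standardizer:
    """Affine z-transform with stored constants for back-transformation."""

    mean: float
    sd: float

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def zstandardize(series, mask=None):
    """z-score a series using its observed cells; return (z, Standardizer).

    ``mask`` flags the observed cells (all observed when omitted).  The
    transform constants come from observed cells only, but the transform is
    applied to every cell, so latent cells stay on a consistent scale.
    """
    x = np.asarray(series, dtype=float)
    m = np.ones(x.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    if m.sum() < 2:
        raise ValueError("z-standardization needs at least 2 observed values")
    mu = float(np.mean(x[m]))
    sd = float(np.std(x[m], ddof=0))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("z-standardization undefined for a constant series")
    st = Standardizer(mu, sd)
    return st.transform(x), st


def time_trend(n_years: int):
    """Centered/scaled year index and its square, decorrelating t from t^2."""
    t = np.arange(1, n_years + 1, dtype=float)
    tz = (t - t.mean()) / t.std(ddof=0)
    return tz, tz ** 2


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EnvSeries:
    """Yearly environmental observations with missingness flags.

    ``harvest`` and ``fish`` are (n_years, 3) arrays in FISHERIES / SPECIES
    column order; ``*_obs`` boolean masks flag observed cells.  Values are
    stored for every cell (a simulator knows the masked truth; a fitter keeps
    the current latent imputation there) -- the flags, not NaNs, carry the
    missingness.  ``rho`` optionally carries the latent hooks-coupling factor.
    """

    years: np.ndarray
    sst: np.ndarray
    harvest: np.ndarray
    fish: np.ndarray
    hooks: np.ndarray
    sst_obs: np.ndarray = None
    harvest_obs: np.ndarray = None
    fish_obs: np.ndarray = None
    hooks_obs: np.ndarray = None
    rho: np.ndarray | None = None

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        n = self.n_years
        if n < 3:
            raise ValueError("need at least 3 years")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be contiguous")
        self.sst = np.asarray(self.sst, dtype=float)
        self.harvest = np.asarray(self.harvest, dtype=float).reshape(n, 3)
        self.fish = np.asarray(self.fish, dtype=float).reshape(n, 3)
        self.hooks = np.asarray(self.hooks, dtype=float)
        for name in ("sst_obs", "harvest_obs", "fish_obs", "hooks_obs"):
            v = getattr(self, name)
            ref = getattr(self, name[:-4])
            setattr(
                self,
                name,
                np.ones(ref.shape, bool) if v is None else np.asarray(v, bool).reshape(ref.shape),
            )
        for m, lab in ((self.harvest_obs, "harvest"), (self.fish_obs, "fish"),
                       (self.hooks_obs[:, None], "hooks"), (self.sst_obs[:, None], "sst")):
            if np.any(m.sum(axis=0) < 3):
                raise ValueError(f"each {lab} series needs >= 3 observed values")

    @property
    def n_years(self) -> int:
        return len(self.years)

    def copy(self) -> "EnvSeries":
        return EnvSeries(
            years=self.years.copy(), sst=self.sst.copy(),
            harvest=self.harvest.copy(), fish=self.fish.copy(),
            hooks=self.hooks.copy(), sst_obs=self.sst_obs.copy(),
            harvest_obs=self.harvest_obs.copy(), fish_obs=self.fish_obs.copy(),
            hooks_obs=self.hooks_obs.copy(),
            rho=None if self.rho is None else self.rho.copy(),
        )

    # -- tidy CSV round trip -------------------------------------------------
    def to_frame(self, blank_unobserved: bool = False) -> pd.DataFrame:
        rows = []
        cols = {
            "sst": (self.sst, self.sst_obs),
            "hooks": (self.hooks, self.hooks_obs),
        }
        for i, j in enumerate(FISHERIES):
            cols[f"harvest_{j}"] = (self.harvest[:, i], self.harvest_obs[:, i])
        for i, k in enumerate(SPECIES):
            cols[f"fish_{k}"] = (self.fish[:, i], self.fish_obs[:, i])
        for var in ENV_VARIABLES:
            vals, obs = cols[var]
            for y, v, o in zip(self.years, vals, obs):
                v_out = np.nan if (blank_unobserved and not o) else v
                rows.append({"year": int(y), "variable": var,
                             "value": v_out, "observed_flag": int(o)})
        return pd.DataFrame(rows)

    def write_csv(self, path, blank_unobserved: bool = False) -> None:
        self.to_frame(blank_unobserved=blank_unobserved).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EnvSeries":
        years = np.sort(df["year"].unique())
        idx = {int(y): i for i, y in enumerate(years)}
        n = len(years)
        data = {v: np.zeros(n) for v in ENV_VARIABLES}
        obs = {v: np.zeros(n, bool) for v in ENV_VARIABLES}
        for _, r in df.iterrows():
            i = idx[int(r["year"])]
            v = r["variable"]
            val = r["value"]
            data[v][i] = 0.0 if pd.isna(val) else float(val)
            obs[v][i] = bool(int(r["observed_flag"]))
        return cls(
            years=years, sst=data["sst"], hooks=data["hooks"],
            harvest=np.column_stack([data[f"harvest_{j}"] for j in FISHERIES]),
            fish=np.column_stack([data[f"fish_{k}"] for k in SPECIES]),
            sst_obs=obs["sst"], hooks_obs=obs["hooks"],
            harvest_obs=np.column_stack([obs[f"harvest_{j}"] for j in FISHERIES]),
            fish_obs=np.column_stack([obs[f"fish_{k}"] for k in SPECIES]),
        )

    @classmethod
    def read_csv(cls, path) -> "EnvSeries":
        return cls.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class HarvestParams:
    """Mean-model coefficients for one landings series (Eq.-1 block)."""

    beta0: float = 0.0
    betaT: float = 0.0
    betaT2: float = 0.0
    betaS: float = 0.0
    phi: float = 0.0
    sigma: float = 1.0
    betaLL_rho: float = 0.0  # hooks-coupling loading; meaningful for LI only

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if abs(self.phi) >= 1:
            raise ValueError("|phi| < 1 required (stationarity)")


@dataclass
class FishParams:
    """Mean-model coefficients for one age-1 production index."""

    beta0: float = 0.0
    betaT: float = 0.0
    betaT2: float = 0.0
    betaS: float = 0.0
    betaTR: float = 0.0
    betaLI: float = 0.0
    phi: float = 0.0
    sigma: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if abs(self.phi) >= 1:
            raise ValueError("|phi| < 1 required (stationarity)")


@dataclass
class HookCoupling:
    """Hooks-deployed observation model and its latent yearly factor loading."""

    beta0: float = 0.0
    phi: float = 0.0
    loading: float = 0.0   # weight of rho_t in the hooks mean
    sigma: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if abs(self.phi) >= 1:
            raise ValueError("|phi| < 1 required (stationarity)")


def _check_pd(S, label):
    S = np.asarray(S, dtype=float)
    if S.shape != (3, 3) or not np.allclose(S, S.T, atol=1e-10):
        raise CovarianceError(f"{label} must be symmetric 3x3")
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise CovarianceError(f"{label} is not positive definite") from exc
    return S


@dataclass
class ResidualCovariance:
    """Within-year residual covariance of a series triple."""

    Sigma_harv: np.ndarray
    Sigma_fish: np.ndarray

    def __post_init__(self):
        self.Sigma_harv = _check_pd(self.Sigma_harv, "Sigma_harv")
        self.Sigma_fish = _check_pd(self.Sigma_fish, "Sigma_fish")

    @classmethod
    def unchecked(cls, Sigma_harv, Sigma_fish):
        """Construction without the PD check (hot paths that validate via
        Cholesky downstream)."""
        obj = cls.__new__(cls)
        obj.Sigma_harv = Sigma_harv
        obj.Sigma_fish = Sigma_fish
        return obj

    @staticmethod
    def from_sd_corr(sd_harv, corr_harv, sd_fish, corr_fish):
        sh, sf = np.asarray(sd_harv, float), np.asarray(sd_fish, float)
        return ResidualCovariance(
            Sigma_harv=np.outer(sh, sh) * np.asarray(corr_harv, float),
            Sigma_fish=np.outer(sf, sf) * np.asarray(corr_fish, float),
        )

    def decompose(self):
        out = {}
        for name, S in (("harv", self.Sigma_harv), ("fish", self.Sigma_fish)):
            sd = np.sqrt(np.diag(S))
            out[name] = (sd, S / np.outer(sd, sd))
        return out


@dataclass
class EnvParams:
    """Full coefficient set of the environmental sub-model.

    ``sst_mean/trend/sd`` drive the exogenous SST generator (linear warming
    trend + noise); they are generator-side only and never fitted.
    """

    harvest: dict = field(default_factory=lambda: {j: HarvestParams() for j in FISHERIES})
    fish: dict = field(default_factory=lambda: {k: FishParams() for k in SPECIES})
    hooks: HookCoupling = field(default_factory=HookCoupling)
    cov: ResidualCovariance = field(
        default_factory=lambda: ResidualCovariance(np.eye(3), np.eye(3))
    )
    sst_mean: float = 20.0
    sst_trend: float = 0.3
    sst_sd: float = 0.15

    def harvest_array(self, attr: str) -> np.ndarray:
        return np.array([getattr(self.harvest[j], attr) for j in FISHERIES])

    def fish_array(self, attr: str) -> np.ndarray:
        return np.array([getattr(self.fish[k], attr) for k in SPECIES])


# ---------------------------------------------------------------------------
# design matrices / deterministic means
# ---------------------------------------------------------------------------

def _covariate_table(env: EnvSeries):
    """z-scored SST + trend columns shared by every mean model.

    Cached on the series object (SST and the year grid never change after
    construction; copies start with a fresh cache)."""
    cache = getattr(env, "_covcache", None)
    if cache is None:
        tz, tz2 = time_trend(env.n_years)
        sstz, sst_st = zstandardize(env.sst, env.sst_obs)
        cache = (tz, tz2, sstz, sst_st)
        env._covcache = cache
    return cache


def _harvest_det(env: EnvSeries, params: EnvParams, rho: np.ndarray | None):
    """Trend+covariate part of the landings means, (n_years, 3)."""
    tz, tz2, sstz, _ = _covariate_table(env)
    m = (params.harvest_array("beta0")[None, :]
         + np.outer(tz, params.harvest_array("betaT"))
         + np.outer(tz2, params.harvest_array("betaT2"))
         + np.outer(sstz, params.harvest_array("betaS")))
    if rho is not None:
        m[:, _LI] += params.harvest[FISHERIES[_LI]].betaLL_rho * np.asarray(rho)
    return m


def _fish_det(env: EnvSeries, params: EnvParams, harv_z: np.ndarray):
    """Trend+covariate part of the production means; lagged landings enter
    z-scored, and the t=1 row has no defined lag (callers drop or zero it)."""
    tz, tz2, sstz, _ = _covariate_table(env)
    m = (params.fish_array("beta0")[None, :]
         + np.outer(tz, params.fish_array("betaT"))
         + np.outer(tz2, params.fish_array("betaT2"))
         + np.outer(sstz, params.fish_array("betaS")))
    lagTR = np.concatenate([[0.0], harv_z[:-1, _TR]])
    lagLI = np.concatenate([[0.0], harv_z[:-1, _LI]])
    m += np.outer(lagTR, params.fish_array("betaTR"))
    m += np.outer(lagLI, params.fish_array("betaLI"))
    return m


def harvest_z(env: EnvSeries):
    """z-scored log-landings columns (covariates for production/demography).

    Cached on the series object; valid because cell values are fixed once a
    series is handed to model code (fitting always works on fresh copies)."""
    cache = getattr(env, "_hzcache", None)
    if cache is None:
        cols, sts = [], []
        for i in range(3):
            z, st = zstandardize(env.harvest[:, i], env.harvest_obs[:, i])
            cols.append(z)
            sts.append(st)
        cache = (np.column_stack(cols), sts)
        env._hzcache = cache
    return cache


def harvest_mean(j, t, params: EnvParams, env: EnvSeries,
                 hooks_term: float = 0.0, hooks_term_prev: float = 0.0):
    """Mean of log-landings for fishery ``j`` in year-index ``t`` (1-based).

    ``hooks_term`` / ``hooks_term_prev`` are the latent coupling factor
    ``rho_t`` at t and t-1 (used by LI only).  The AR1 term uses the previous
    year's deviation of observed landings from the trend+covariate
    expectation; at t=1 it is defined as 0.
    """
    ji = FISHERIES.index(j) if isinstance(j, str) else int(j)
    p = params.harvest[FISHERIES[ji]]
    tz, tz2, sstz, _ = _covariate_table(env)
    i = t - 1

    def det(ii, rho_ii):
        m = p.beta0 + p.betaT * tz[ii] + p.betaT2 * tz2[ii] + p.betaS * sstz[ii]
        if ji == _LI:
            m += p.betaLL_rho * rho_ii
        return m

    m_t = det(i, hooks_term)
    if t >= 2:
        m_t += p.phi * (det(i - 1, hooks_term_prev) - env.harvest[i - 1, ji])
    return float(m_t)


def fish_mean(k, t, params: EnvParams, env: EnvSeries):
    """Mean of log-production for species ``k`` in year-index ``t`` (1-based)."""
    ki = SPECIES.index(k) if isinstance(k, str) else int(k)
    p = params.fish[SPECIES[ki]]
    tz, tz2, sstz, _ = _covariate_table(env)
    i = t - 1

    def det(ii, hz):
        m = p.beta0 + p.betaT * tz[ii] + p.betaT2 * tz2[ii] + p.betaS * sstz[ii]
        if ii >= 1:
            m += p.betaTR * hz[ii - 1, _TR] + p.betaLI * hz[ii - 1, _LI]
        return m

    m_t = p.beta0 + p.betaT * tz[i] + p.betaT2 * tz2[i] + p.betaS * sstz[i]
    if t >= 2:
        if not (env.harvest_obs[i - 1, _TR] and env.harvest_obs[i - 1, _LI]):
            raise ValueError(
                f"lagged landings for year-index {t} are missing; impute first"
            )
        hz, _ = harvest_z(env)
        m_t = det(i, hz) + p.phi * (det(i - 1, hz) - env.fish[i - 1, ki])
    return float(m_t)


def _all_means(env: EnvSeries, params: EnvParams, rho):
    """Full-mean matrices (AR1 included) for landings, production and hooks.

    Uses the cell *values* stored in ``env`` for lags, so on a completed
    series every row is defined.
    """
    n = env.n_years
    mh_det = _harvest_det(env, params, rho)
    phis_h = params.harvest_array("phi")
    mu_h = mh_det.copy()
    mu_h[1:] += phis_h[None, :] * (mh_det[:-1] - env.harvest[:-1])

    hz, _ = harvest_z(env)
    mf_det = _fish_det(env, params, hz)
    phis_f = params.fish_array("phi")
    mu_f = mf_det.copy()
    mu_f[1:] += phis_f[None, :] * (mf_det[:-1] - env.fish[:-1])

    hk = params.hooks
    rr = np.zeros(n) if rho is None else np.asarray(rho, float)
    mk_det = hk.beta0 + hk.loading * rr
    mu_k = mk_det.copy()
    mu_k[1:] += hk.phi * (mk_det[:-1] - env.hooks[:-1])
    return mu_h, mu_f, mu_k


def env_loglik(env: EnvSeries, params: EnvParams, rho=None, complete: bool = False):
    """Joint log-density of the environmental series under the path model.

    Sums (i) the MVN density of yearly landings-residual triples under
    Sigma_harv, (ii) the same for production triples under Sigma_fish,
    (iii) the normal density of hooks, and (iv) the standard-normal prior of
    the latent coupling factor ``rho_t`` when supplied.

    With ``complete=False`` only observed cells enter (partially observed
    triples use the marginal MVN of the observed sub-vector); lagged values
    feeding an observed cell must themselves be observed.  With
    ``complete=True`` every cell enters -- the joint density of observed and
    latent cells used during fitting.
    """
    mu_h, mu_f, mu_k = _all_means(env, params, rho)
    Sh, Sf = params.cov.Sigma_harv, params.cov.Sigma_fish
    if complete:  # vectorized joint density of all cells (fitting hot path);
        # a non-PD covariance surfaces as a Cholesky failure below
        try:
            ll = mvn_rows_loglik(env.harvest - mu_h, Sh)
            ll += mvn_rows_loglik(env.fish - mu_f, Sf)
        except np.linalg.LinAlgError as exc:
            raise CovarianceError(str(exc)) from exc
        z = (env.hooks - mu_k) / params.hooks.sigma
        ll += float(np.sum(-0.5 * z ** 2 - np.log(params.hooks.sigma)
                           - 0.5 * np.log(2 * np.pi)))
        if rho is not None:
            r = np.asarray(rho, float)
            ll += float(np.sum(-0.5 * r ** 2 - 0.5 * np.log(2 * np.pi)))
        return float(ll)
    _check_pd(Sh, "Sigma_harv")
    _check_pd(Sf, "Sigma_fish")
    ll = 0.0

    def triple_term(resid, obs, Sigma, lag_ok):
        out = 0.0
        n = resid.shape[0]
        for t in range(n):
            m = np.ones(3, bool) if complete else obs[t]
            if not complete and t >= 1 and not lag_ok[t - 1]:
                m = np.zeros(3, bool)  # lag not defined -> cell left latent
            if not m.any():
                continue
            sub = Sigma[np.ix_(m, m)]
            out += stats.multivariate_normal.logpdf(resid[t, m], mean=np.zeros(m.sum()), cov=sub)
        return out

    # a landings/production cell's AR1 lag needs its own series' previous cell
    lag_h = env.harvest_obs.all(axis=1)
    lag_f = env.fish_obs.all(axis=1) & np.concatenate([[True], lag_h[:-1]])
    ll += triple_term(env.harvest - mu_h, env.harvest_obs, Sh, lag_h)
    ll += triple_term(env.fish - mu_f, env.fish_obs, Sf, lag_f)

    sig_k = params.hooks.sigma
    for t in range(env.n_years):
        use = complete or (env.hooks_obs[t] and (t == 0 or env.hooks_obs[t - 1]))
        if use:
            ll += stats.norm.logpdf(env.hooks[t], mu_k[t], sig_k)
    if rho is not None:
        ll += float(np.sum(stats.norm.logpdf(np.asarray(rho, float))))
    return float(ll)


def mvn_rows_loglik(resid: np.ndarray, Sigma: np.ndarray) -> float:
    """Sum of MVN(0, Sigma) log-densities over the rows of ``resid``."""
    L = np.linalg.cholesky(Sigma)
    z = np.linalg.solve(L, resid.T)
    k = Sigma.shape[0]
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    n = resid.shape[0]
    return float(-0.5 * np.sum(z ** 2) - 0.5 * n * (logdet + k * np.log(2 * np.pi)))


# ---------------------------------------------------------------------------
# model-based completion of missing years
# ---------------------------------------------------------------------------

def _conditional_mvn(mu, Sigma, obs_mask, y_obs):
    """Mean/cov of the missing block of an MVN given the observed block."""
    mi = ~obs_mask
    if not obs_mask.any():
        return mu[mi], Sigma[np.ix_(mi, mi)]
    Soo = Sigma[np.ix_(obs_mask, obs_mask)]
    Smo = Sigma[np.ix_(mi, obs_mask)]
    w = np.linalg.solve(Soo, y_obs - mu[obs_mask])
    cmu = mu[mi] + Smo @ w
    ccov = Sigma[np.ix_(mi, mi)] - Smo @ np.linalg.solve(Soo, Smo.T)
    return cmu, ccov


def impute_missing(env: EnvSeries, params: EnvParams, rho=None, rng=None):
    """Return a completed copy of ``env`` with missing cells drawn from the model.

    A single forward pass per call: each missing landings/production cell is
    drawn from its conditional normal given same-year observed siblings (via
    the residual covariance) and the (possibly just-imputed) previous year;
    hooks are drawn from their AR1 + latent-factor model, which is how the
    pre-1993 effort years are reconstructed from the landings coupling.
    Observed cells are never touched; a fully observed input returns an
    identical copy.  ``rho`` defaults to the stored latent factor, else zero.
    Call repeatedly for a predictive ensemble.
    """
    rng = np.random.default_rng(rng)
    out = env.copy()
    if rho is None:
        rho = env.rho if env.rho is not None else np.zeros(env.n_years)
    rho = np.asarray(rho, float)
    tz, tz2, sstz, _ = _covariate_table(env)
    Sh, Sf = params.cov.Sigma_harv, params.cov.Sigma_fish
    mh_det = _harvest_det(out, params, rho)
    phis_h = params.harvest_array("phi")
    phis_f = params.fish_array("phi")
    hk = params.hooks
    mk_det = hk.beta0 + hk.loading * rho

    # landings first (production depends on their lags), then hooks
    for t in range(out.n_years):
        mu_t = mh_det[t].copy()
        if t >= 1:
            mu_t += phis_h * (mh_det[t - 1] - out.harvest[t - 1])
        m = out.harvest_obs[t]
        if not m.all():
            cmu, ccov = _conditional_mvn(mu_t, Sh, m, out.harvest[t, m])
            draw = rng.multivariate_normal(cmu, ccov) if cmu.size else cmu
            out.harvest[t, ~m] = draw

    hz, _ = harvest_z(out)
    mf_det = _fish_det(out, params, hz)
    for t in range(out.n_years):
        mu_t = mf_det[t].copy()
        if t >= 1:
            mu_t += phis_f * (mf_det[t - 1] - out.fish[t - 1])
        m = out.fish_obs[t]
        if not m.all():
            cmu, ccov = _conditional_mvn(mu_t, Sf, m, out.fish[t, m])
            draw = rng.multivariate_normal(cmu, ccov) if cmu.size else cmu
            out.fish[t, ~m] = draw

    for t in range(out.n_years):
        if not out.hooks_obs[t]:
            mu_t = mk_det[t]
            if t >= 1:
                mu_t += hk.phi * (mk_det[t - 1] - out.hooks[t - 1])
            out.hooks[t] = mu_t + (hk.sigma * rng.standard_normal() if hk.sigma > 0 else 0.0)
    return out
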