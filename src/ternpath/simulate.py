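"""Synthetic-data generator.

Stands in for the six-decade banding dataset: it draws environmental series
from the path model and individual fates/encounters from the multistate
Barker process at known ("true") parameters, so every downstream stage can be
tested against a known answer.  The defaults emulate the study system --
~2 x 10^4 chicks banded per year across two natal states, breeding-ground
detectability of order 10^-3, dead-recovery probability ~0.014, non-breeding
resight ~2 x 10^-3, strong age structure in survival (first-year ~0.31,
adult ~0.81), small band-type effects, and high fidelity (F ~ 0.998,
psi ~ 0.984).

``expected_marray`` provides the closed-form first-reencounter expectation
(the classic m-array, extended with event types) used as a Monte-Carlo
oracle for the simulator and the likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import barker, env as envmod
from .barker import (
    BAND_TYPES,
    NATAL_STATES,
    DemographicParams,
    DetectionParams,
    EncounterHistoryRecord,
    MovementParams,
    RealizedRates,
    SurvivalParams,
    YearEffects,
    build_matrices,
    hazard_to_survival_inverse,
    realized_rates,
)
from .env import (
    EnvParams,
    EnvSeries,
    FishParams,
    HarvestParams,
    HookCoupling,
    ResidualCovariance,
)

DEFAULT_SEED = 20221022


# ---------------------------------------------------------------------------
# true parameter set
# ---------------------------------------------------------------------------

@dataclass
class TrueParameterSet:
    """Generating parameters for one synthetic study."""

    env_params: EnvParams
    demo_params: DemographicParams
    n_years: int
    start_year: int
    releases: pd.DataFrame   # columns: year, natal_state, band_type, n
    seed: int = DEFAULT_SEED
    #: per-series missing-year ranges, as offsets [start, stop) from year 1
    missing: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3")
        rel = self.releases
        if (rel["n"] < 0).any() or not np.issubdtype(rel["n"].dtype, np.integer):
            raise ValueError("releases must be non-negative integers")
        years = set(range(self.start_year, self.start_year + self.n_years))
        if not set(rel["year"]).issubset(years):
            raise ValueError("release years outside the study span")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)


def default_releases(n_years: int, start_year: int, per_year: int = 20000) -> pd.DataFrame:
    """Release schedule shaped like the study's banding effort.

    70% of chicks are banded in NC, 30% in VA; all receive service bands
    except five scattered years in which 10% of each state's chicks get
    early-ancillary markers, and the last four years in which 25% of VA
    chicks get plastic field-readable (PFR) bands.
    """
    rows = []
    ancillary_years = {int(round(f * (n_years - 1))) for f in (0.23, 0.3, 0.5, 0.55, 0.6)}
    for i in range(n_years):
        y = start_year + i
        n_nc, n_va = int(0.7 * per_year), per_year - int(0.7 * per_year)
        for state, n_state in (("NC", n_nc), ("VA", n_va)):
            n_anc = int(0.1 * n_state) if i in ancillary_years else 0
            n_pfr = int(0.25 * n_state) if (state == "VA" and i >= n_years - 4) else 0
            rows.append({"year": y, "natal_state": state, "band_type": "service",
                         "n": n_state - n_anc - n_pfr})
            if n_anc:
                rows.append({"year": y, "natal_state": state,
                             "band_type": "ancillary", "n": n_anc})
            if n_pfr:
                rows.append({"year": y, "natal_state": state,
                             "band_type": "PFR", "n": n_pfr})
    return pd.DataFrame(rows)


def default_env_params() -> EnvParams:
    """Study-shaped environmental truth (coefficients on z-scaled covariates,
    responses on the log scale)."""
    harvest = {
        "CR": HarvestParams(beta0=11.0, betaT=0.5, betaT2=-0.8, betaS=-0.15,
                            phi=0.4, sigma=0.18),
        "LI": HarvestParams(beta0=10.0, betaT=-0.2, betaT2=0.7, betaS=0.0,
                            phi=0.4, sigma=0.20, betaLL_rho=-0.10),
        "TR": HarvestParams(beta0=13.0, betaT=-1.2, betaT2=0.05, betaS=0.0,
                            phi=0.4, sigma=0.15),
    }
    fish = {
        "MN": FishParams(beta0=20.0, betaT=0.5, betaT2=-1.0, betaS=-0.10,
                         betaTR=-0.15, betaLI=0.30, phi=0.3, sigma=0.25),
        "DM": FishParams(beta0=16.0, betaT=1.0, betaT2=-0.4, betaS=0.05,
                         betaTR=-0.10, betaLI=0.0, phi=0.3, sigma=0.30),
        "HR": FishParams(beta0=19.0, betaT=0.3, betaT2=0.8, betaS=-0.10,
                         betaTR=-0.20, betaLI=-0.20, phi=0.3, sigma=0.25),
    }
    corr_h = np.array([[1.0, -0.09, -0.18], [-0.09, 1.0, -0.15], [-0.18, -0.15, 1.0]])
    corr_f = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.42], [0.0, 0.42, 1.0]])
    cov = ResidualCovariance.from_sd_corr(
        [harvest[j].sigma for j in envmod.FISHERIES], corr_h,
        [fish[k].sigma for k in envmod.SPECIES], corr_f,
    )
    return EnvParams(harvest=harvest, fish=fish,
                     hooks=HookCoupling(beta0=16.0, phi=0.5, loading=0.30, sigma=0.10),
                     cov=cov, sst_mean=20.0, sst_trend=0.3, sst_sd=0.15)


def default_demo_params() -> DemographicParams:
    """Study-shaped demographic truth.

    Mean age-specific survival 0.31 / 0.60 / 0.85 / 0.83 / 0.81 (ages 1, 2,
    3, 4, 5+); supported hazard covariates: SST on pre-breeders (+), hooks on
    sub-adults (+), menhaden on sub-adults/adults (-); senescence omitted
    (subtle in the source system).
    """
    S_by_age = {1: 0.31, 2: 0.60, 3: 0.85, 4: 0.83, 5: 0.81}
    eps = {a: float(hazard_to_survival_inverse(s)) for a, s in S_by_age.items()}
    beta0_A = np.array([eps[1], eps[3], eps[5]])
    beta_age = np.zeros(barker.MAX_AGE)
    beta_age[1] = eps[2] - eps[1]   # age 2 relative to class ref (age 1)
    beta_age[3] = eps[4] - eps[3]   # age 4 relative to age 3
    beta_x = np.zeros((3, len(barker.HAZARD_COVARIATES)))
    cov_idx = {c: i for i, c in enumerate(barker.HAZARD_COVARIATES)}
    beta_x[0, cov_idx["SST"]] = 0.12
    beta_x[1, cov_idx["HK"]] = 0.15
    beta_x[1, cov_idx["MN"]] = -0.10
    beta_x[2, cov_idx["MN"]] = -0.15
    sd_A = np.array([0.15, 0.12, 0.10])
    corr_A = np.full((3, 3), 0.5)
    np.fill_diagonal(corr_A, 1.0)
    survival = SurvivalParams(beta0_A=beta0_A, beta_age=beta_age, beta_x_A=beta_x,
                              Sigma_A=np.outer(sd_A, sd_A) * corr_A)
    det = DetectionParams()
    ridx = {c: i for i, c in enumerate(barker.RECOVERY_COVARIATES)}
    det.r_beta_x[ridx["DM"]] = -0.10
    det.r_beta_x[ridx["TR"]] = 0.10
    return DemographicParams(survival=survival, movement=MovementParams(),
                             detection=det)


def default_truth(n_years: int = 30, start_year: int = 1990,
                  per_year: int = 20000, seed: int = DEFAULT_SEED) -> TrueParameterSet:
    """Desk-scale default scenario: 30 years, 2 natal states, 20,000
    releases/year, with missing-year ranges mimicking the study's
    (landings missing at the end, production at both ends, effort for the
    first half of the series)."""
    n_missing_tail = max(2, n_years // 10)
    missing = {
        "harvest": [[n_years - n_missing_tail, n_years]],
        "fish": [[0, max(2, n_years // 10)], [n_years - n_missing_tail, n_years]],
        "hooks": [[0, n_years // 2]],
    }
    return TrueParameterSet(
        env_params=default_env_params(),
        demo_params=default_demo_params(),
        n_years=n_years,
        start_year=start_year,
        releases=default_releases(n_years, start_year, per_year),
        seed=seed,
        missing=missing,
    )


# ---------------------------------------------------------------------------
# environment generation
# ---------------------------------------------------------------------------

def gen_environment(truth: TrueParameterSet, seed=None) -> EnvSeries:
    """Draw one environmental realization from the path model.

    SST is exogenous: linear warming trend + Gaussian noise.  Landings and
    production are generated from their full mean models with
    Sigma-correlated within-year residual triples; hooks through the shared
    latent coupling factor.  Missing-year masks are applied afterwards (the
    masked truth stays in the cells; the ``*_obs`` flags carry missingness).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    p = truth.env_params
    n = truth.n_years
    if n < 3:
        raise ValueError("n_years too short")
    tz, tz2 = envmod.time_trend(n)

    sst = p.sst_mean + p.sst_trend * tz + p.sst_sd * rng.standard_normal(n)
    sstz = (sst - sst.mean()) / sst.std(ddof=0) if sst.std(ddof=0) > 0 else np.zeros(n)
    rho = rng.standard_normal(n)

    Lh = np.linalg.cholesky(envmod._check_pd(p.cov.Sigma_harv, "Sigma_harv"))
    Lf = np.linalg.cholesky(envmod._check_pd(p.cov.Sigma_fish, "Sigma_fish"))

    b0 = p.harvest_array("beta0")
    bT = p.harvest_array("betaT")
    bT2 = p.harvest_array("betaT2")
    bS = p.harvest_array("betaS")
    phis = p.harvest_array("phi")
    bLL = p.harvest[envmod.FISHERIES[envmod._LI]].betaLL_rho
    m_det = (b0[None, :] + np.outer(tz, bT) + np.outer(tz2, bT2) + np.outer(sstz, bS))
    m_det[:, envmod._LI] += bLL * rho
    harvest = np.zeros((n, 3))
    eps_h = (Lh @ rng.standard_normal((3, n))).T
    for t in range(n):
        mu = m_det[t].copy()
        if t >= 1:
            mu += phis * (m_det[t - 1] - harvest[t - 1])
        harvest[t] = mu + eps_h[t]

    # z-scale lagged-landings covariates with the constants a fitter will see
    # (observed cells only), so generating and fitted coefficients agree
    harvest_obs = np.ones((n, 3), bool)
    for lo, hi in truth.missing.get("harvest", []):
        harvest_obs[lo:hi] = False
    hz = np.column_stack([
        (harvest[:, i] - harvest[harvest_obs[:, i], i].mean())
        / harvest[harvest_obs[:, i], i].std(ddof=0)
        for i in range(3)])
    f0 = p.fish_array("beta0")
    fT = p.fish_array("betaT")
    fT2 = p.fish_array("betaT2")
    fS = p.fish_array("betaS")
    fTR = p.fish_array("betaTR")
    fLI = p.fish_array("betaLI")
    fphi = p.fish_array("phi")
    f_det = (f0[None, :] + np.outer(tz, fT) + np.outer(tz2, fT2) + np.outer(sstz, fS))
    lagTR = np.concatenate([[0.0], hz[:-1, envmod._TR]])
    lagLI = np.concatenate([[0.0], hz[:-1, envmod._LI]])
    f_det += np.outer(lagTR, fTR) + np.outer(lagLI, fLI)
    fish = np.zeros((n, 3))
    eps_f = (Lf @ rng.standard_normal((3, n))).T
    for t in range(n):
        mu = f_det[t].copy()
        if t >= 1:
            mu += fphi * (f_det[t - 1] - fish[t - 1])
        fish[t] = mu + eps_f[t]

    hk = p.hooks
    mk_det = hk.beta0 + hk.loading * rho
    hooks = np.zeros(n)
    for t in range(n):
        mu = mk_det[t]
        if t >= 1:
            mu += hk.phi * (mk_det[t - 1] - hooks[t - 1])
        hooks[t] = mu + hk.sigma * rng.standard_normal()

    harvest_obs = np.ones((n, 3), bool)
    fish_obs = np.ones((n, 3), bool)
    hooks_obs = np.ones(n, bool)
    for lo, hi in truth.missing.get("harvest", []):
        harvest_obs[lo:hi] = False
    for lo, hi in truth.missing.get("fish", []):
        fish_obs[lo:hi] = False
    for lo, hi in truth.missing.get("hooks", []):
        hooks_obs[lo:hi] = False

    return EnvSeries(years=truth.years, sst=sst, harvest=harvest, fish=fish,
                     hooks=hooks, harvest_obs=harvest_obs, fish_obs=fish_obs,
                     hooks_obs=hooks_obs, rho=rho)


# ---------------------------------------------------------------------------
# demographic generation
# ---------------------------------------------------------------------------

def draw_year_effects(truth: TrueParameterSet, rng) -> YearEffects:
    """Draw the latent yearly deviations of the demographic sub-model."""
    n = truth.n_years
    sv, dt = truth.demo_params.survival, truth.demo_params.detection
    return YearEffects(
        hazard=rng.multivariate_normal(np.zeros(3), sv.Sigma_A, size=n),
        u_r=dt.sigma_r * rng.standard_normal(n),
        u_R=dt.sigma_R * rng.standard_normal(n),
        u_p=rng.multivariate_normal(np.zeros(2), dt.Sigma_p, size=n),
    )


@dataclass
class SimulatedStudy:
    """One synthetic study: environment, histories, per-bird truth."""

    env: EnvSeries
    histories: list
    latent_states: dict          # (year, natal, band) -> (N, n_years) int8
    effects: YearEffects
    rates: RealizedRates
    truth: TrueParameterSet

    @property
    def n_released(self) -> int:
        return int(self.truth.releases["n"].sum())


def _simulate_group(rel_idx, natal_idx, band_idx, n_birds, rates, n_years, rng):
    """Forward-simulate one (cohort, natal, band) group; returns states and
    events matrices (pre-release cells are 0 in events, -1 in states)."""
    states = np.full((n_birds, n_years), -1, dtype=np.int8)
    events = np.zeros((n_birds, n_years), dtype=np.int8)
    states[:, rel_idx] = natal_idx
    for t in range(rel_idx + 1, n_years):
        a = min(t - rel_idx, barker.MAX_AGE)
        S = rates.S[a - 1, t - 1]
        r = rates.r[t - 1, natal_idx, band_idx]
        Rlag = rates.R[t - 1, natal_idx, band_idx]
        Rplag = rates.Rp[t - 1, natal_idx, band_idx]
        move_ok = a >= rates.min_move_age
        F = rates.F if move_ok else 1.0
        psi = rates.psi if move_ok else 1.0

        prev = states[:, t - 1]
        cur = np.full(n_birds, 5, dtype=np.int8)
        live = prev <= 2
        u = rng.random(n_birds)
        surv = live & (u < S)
        dead_now = live & ~surv
        u2 = rng.random(n_birds)
        cur[dead_now] = np.where(u2[dead_now] < r, 3, 4)
        # movement among survivors from breeding states
        breed = surv & (prev <= 1)
        u3 = rng.random(n_birds)
        u4 = rng.random(n_birds)
        stay_meta = u3 < F
        stay_state = u4 < psi
        cur[breed & stay_meta & stay_state] = prev[breed & stay_meta & stay_state]
        sw = breed & stay_meta & ~stay_state
        cur[sw] = 1 - prev[sw]
        cur[breed & ~stay_meta] = 2
        cur[surv & (prev == 2)] = 2
        states[:, t] = cur

        ev = np.full(n_birds, 6, dtype=np.int8)
        pN = rates.alpha[a] * rates.p[t, 0, band_idx]
        pV = rates.alpha[a] * rates.p[t, 1, band_idx]
        ub = rng.random(n_birds)
        uf = rng.random(n_birds)
        in_nc, in_va = cur == 0, cur == 1
        seenb = (in_nc & (ub < pN)) | (in_va & (ub < pV))
        seenf = (cur <= 2) & (uf < Rlag)
        ev[in_nc & seenb & seenf] = 1
        ev[in_va & seenb & seenf] = 2
        ev[in_nc & seenb & ~seenf] = 3
        ev[in_va & seenb & ~seenf] = 4
        ev[(cur <= 2) & ~seenb & seenf] = 5
        ev[cur == 3] = 7
        died_unrec = cur == 4
        ev[died_unrec] = np.where(rng.random(n_birds)[died_unrec] < Rplag, 5, 6)
        events[:, t] = ev

    # silence after a dead recovery
    rec = events == 7
    has_rec = rec.any(axis=1)
    if has_rec.any():
        first = np.argmax(rec, axis=1)
        col = np.arange(n_years)[None, :]
        events[has_rec[:, None] & (col > first[:, None])] = 0
    return states, events


def gen_histories(truth: TrueParameterSet, env: EnvSeries, seed=None) -> SimulatedStudy:
    """Simulate every released chick through the six-state chain and the
    seven-event observation process, then compress identical histories."""
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    env_years = set(int(y) for y in env.years)
    if not set(int(y) for y in truth.releases["year"]).issubset(env_years):
        raise ValueError("release year outside the environmental series")
    effects = draw_year_effects(truth, rng)
    rates = realized_rates(truth.demo_params, env, effects)
    n_years = env.n_years
    year_of = {int(y): i for i, y in enumerate(env.years)}

    histories = []
    latent = {}
    for _, row in truth.releases.iterrows():
        n_birds = int(row["n"])
        if n_birds == 0:
            continue
        rel_idx = year_of[int(row["year"])]
        ni = NATAL_STATES.index(row["natal_state"])
        bi = BAND_TYPES.index(row["band_type"])
        states, events = _simulate_group(rel_idx, ni, bi, n_birds, rates, n_years, rng)
        latent[(int(row["year"]), row["natal_state"], row["band_type"])] = states
        uniq, counts = np.unique(events, axis=0, return_counts=True)
        for ev, c in zip(uniq, counts):
            histories.append(EncounterHistoryRecord(
                int(row["year"]), row["natal_state"], row["band_type"],
                ev.copy(), int(c)))
    return SimulatedStudy(env=env, histories=histories, latent_states=latent,
                          effects=effects, rates=rates, truth=truth)


def simulate_study(truth: TrueParameterSet, seed=None) -> SimulatedStudy:
    """gen_environment + gen_histories in one call."""
    base = truth.seed if seed is None else seed
    env = gen_environment(truth, base)
    return gen_histories(truth, env, base + 1)


# ---------------------------------------------------------------------------
# closed-form first-reencounter expectations (extended m-array)
# ---------------------------------------------------------------------------

def expected_marray(truth: TrueParameterSet, env: EnvSeries,
                    rates: RealizedRates | None = None) -> pd.DataFrame:
    """Exact expected first-reencounter counts per cohort group.

    Rows: (cohort_year, natal_state, band_type, year, event) expected counts
    for observable events (1-5, 7) plus one ``never`` row per group.  The
    cells of a group sum to its release count (multinomial closure).  Pass
    the ``rates`` realized in a simulation to get its exact expectation;
    defaults to zero year effects.
    """
    if rates is None:
        rates = realized_rates(truth.demo_params, env, YearEffects.zeros(env.n_years))
    Psi, Omega = build_matrices(rates, env.n_years)
    year_of = {int(y): i for i, y in enumerate(env.years)}
    rows = []
    for _, rrow in truth.releases.iterrows():
        N = int(rrow["n"])
        rel = year_of[int(rrow["year"])]
        ni = NATAL_STATES.index(rrow["natal_state"])
        bi = BAND_TYPES.index(rrow["band_type"])
        u = np.zeros(barker.N_STATES)
        u[ni] = 1.0
        for t in range(rel + 1, env.n_years):
            a = min(t - rel, barker.MAX_AGE)
            u = u @ Psi[t - 1, a - 1, ni, bi]
            O = Omega[t, a - 1, ni, bi]
            for e in (1, 2, 3, 4, 5, 7):
                pe = float(u @ O[:, e - 1])
                if pe > 0:
                    rows.append({"cohort_year": int(rrow["year"]),
                                 "natal_state": rrow["natal_state"],
                                 "band_type": rrow["band_type"],
                                 "year": int(env.years[t]), "event": e,
                                 "expected": N * pe})
            u = u * O[:, 5]
        rows.append({"cohort_year": int(rrow["year"]),
                     "natal_state": rrow["natal_state"],
                     "band_type": rrow["band_type"],
                     "year": 0, "event": 0, "expected": N * float(u.sum())})
    return pd.DataFrame(rows)


def observed_marray(study: SimulatedStudy) -> pd.DataFrame:
    """First-reencounter counts realized in a simulated study."""
    counts: dict = {}
    year = study.env.years
    for rec in study.histories:
        ev = rec.events
        seen = np.where((ev != 0) & (ev != 6))[0]
        if len(seen) == 0:
            key = (rec.release_year, rec.natal_state, rec.band_type, 0, 0)
        else:
            t = int(seen[0])
            key = (rec.release_year, rec.natal_state, rec.band_type,
                   int(year[t]), int(ev[t]))
        counts[key] = counts.get(key, 0) + rec.count
    return pd.DataFrame(
        [{"cohort_year": k[0], "natal_state": k[1], "band_type": k[2],
          "year": k[3], "event": k[4], "count": v} for k, v in counts.items()]
    )


# ---------------------------------------------------------------------------
# truth (de)serialization
# ---------------------------------------------------------------------------

def truth_to_json(truth: TrueParameterSet, path=None) -> str:
    def enc(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    d = {
        "env_params": {
            "harvest": {j: asdict(truth.env_params.harvest[j]) for j in envmod.FISHERIES},
            "fish": {k: asdict(truth.env_params.fish[k]) for k in envmod.SPECIES},
            "hooks": asdict(truth.env_params.hooks),
            "Sigma_harv": truth.env_params.cov.Sigma_harv,
            "Sigma_fish": truth.env_params.cov.Sigma_fish,
            "sst_mean": truth.env_params.sst_mean,
            "sst_trend": truth.env_params.sst_trend,
            "sst_sd": truth.env_params.sst_sd,
        },
        "demo_params": {
            "survival": asdict(truth.demo_params.survival),
            "movement": asdict(truth.demo_params.movement),
            "detection": asdict(truth.demo_params.detection),
        },
        "n_years": truth.n_years,
        "start_year": truth.start_year,
        "seed": truth.seed,
        "missing": truth.missing,
        "releases": truth.releases.to_dict(orient="list"),
    }
    text = json.dumps(d, default=enc, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def truth_from_json(source) -> TrueParameterSet:
    if isinstance(source, str) and source.lstrip().startswith("{"):
        d = json.loads(source)
    else:
        with open(source) as fh:
            d = json.load(fh)
    ep = d["env_params"]
    env_params = EnvParams(
        harvest={j: HarvestParams(**ep["harvest"][j]) for j in envmod.FISHERIES},
        fish={k: FishParams(**ep["fish"][k]) for k in envmod.SPECIES},
        hooks=HookCoupling(**ep["hooks"]),
        cov=ResidualCovariance(np.array(ep["Sigma_harv"]), np.array(ep["Sigma_fish"])),
        sst_mean=ep["sst_mean"], sst_trend=ep["sst_trend"], sst_sd=ep["sst_sd"],
    )
    dp = d["demo_params"]
    demo = DemographicParams(
        survival=SurvivalParams(**{k: np.array(v) if isinstance(v, list) else v
                                   for k, v in dp["survival"].items()}),
        movement=MovementParams(**dp["movement"]),
        detection=DetectionParams(**{k: np.array(v) if isinstance(v, list) else v
                                     for k, v in dp["detection"].items()}),
    )
    releases = pd.DataFrame(d["releases"]).astype({"n": int, "year": int})
    return TrueParameterSet(env_params=env_params, demo_params=demo,
                            n_years=d["n_years"], start_year=d["start_year"],
                            releases=releases, seed=d["seed"],
                            missing={k: [list(r) for r in v] for k, v in d["missing"].items()})
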