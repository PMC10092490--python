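"""Marginalized multistate Barker mark-recapture-recovery model.

The latent process tracks each banded chick through six states per year:

====  =======================================================================
1     alive, in the North Carolina (NC) breeding population
2     alive, in the Virginia (VA) breeding population
3     alive, permanently emigrated from the mid-Atlantic metapopulation
4     died during the most recent interval and was recovered/reported dead
5     died during the most recent interval, not recovered
6     died during a previous interval (terminal)
====  =======================================================================

Transitions among living states combine true survival ``S`` (an age- and
year-specific complementary log-log hazard) with two constant fidelity
parameters: ``F`` (stay in the mid-Atlantic metapopulation) and ``psi`` (stay
in the natal/current state within it); movement is disallowed below the
minimum breeding age.  Transitions into the dead states split mortality
``1 - S`` by the recovery probability ``r``.  Dead-state transitions are
unidirectional into state 6.

Each year a single categorical event (1-7) is emitted:

====  =======================================================================
1/2   seen on the NC/VA breeding grounds *and* in Florida that cycle
3/4   seen on the NC/VA breeding grounds only
5     seen in Florida (non-breeding) only
6     not seen
7     recovered dead
====  =======================================================================

Breeding-ground detection is availability x detectability (``alpha * p_hat``),
Florida resight is ``R`` for survivors and ``R'`` for birds that died during
the interval (emitted from state 5; recovery takes precedence for state 4).
The likelihood marginalizes the latent state sequence with a scaled forward
pass, so identical histories can be compressed with multiplicities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product as _iproduct

import numpy as np
import pandas as pd

from .env import EnvSeries, harvest_z, zstandardize

try:  # optional compiled forward kernel
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is present in the tested stack
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


N_STATES = 6
N_EVENTS = 7
MAX_AGE = 25  # older birds jointly inform the oldest modelled age

NATAL_STATES = ("NC", "VA")
BAND_TYPES = ("service", "ancillary", "PFR")

#: hazard / recovery covariate columns (z-scored env series)
HAZARD_COVARIATES = ("SST", "CR", "LI", "TR", "HK", "MN", "DM", "HR")
#: the recovery model uses harvest-pressure and production covariates only
RECOVERY_COVARIATES = ("CR", "LI", "TR", "HK", "MN", "DM", "HR")

AGE_CLASSES = ("PB", "SA", "AD")  # pre-breeder (1-2), sub-adult (3-4), adult (5+)


def age_class(age: int) -> int:
    """Map a single age in years to its age-class index."""
    if age <= 2:
        return 0
    if age <= 4:
        return 1
    return 2


AGE_CLASS_OF = np.array([age_class(a) for a in range(1, MAX_AGE + 1)])


# ---------------------------------------------------------------------------
# elemental rate functions
# ---------------------------------------------------------------------------

def survival_from_hazard(epsilon):
    """Survival probability from a log-scale mortality hazard:
    ``S = exp(-exp(eps))``, strictly decreasing in ``eps``."""
    return np.exp(-np.exp(np.asarray(epsilon, dtype=float)))


def hazard_to_survival_inverse(S):
    """Inverse map ``eps = log(-log S)`` (handy for setting intercepts)."""
    return np.log(-np.log(np.asarray(S, dtype=float)))


def availability(age: int, alpha_hat) -> float:
    """Conditional breeding propensity: 0 below age 2, estimated for ages
    2-6, and 1 from the seventh year (full breeding adults)."""
    if age < 2:
        return 0.0
    if age >= 7:
        return 1.0
    return float(alpha_hat[age] if isinstance(alpha_hat, dict) else alpha_hat[age - 2])


def rprime(R, rule: str = "half"):
    """Florida resight probability in the interval of death.

    ``"half"`` (default): ``R/2`` -- deaths fall, on average, halfway through
    the non-breeding season.  ``"square"``: ``R**2``.  Both readings of the
    source constraint are supported and config-selectable.
    """
    R = np.asarray(R, dtype=float)
    if rule == "half":
        return R / 2.0
    if rule == "square":
        return R ** 2
    raise ValueError(f"unknown R' rule: {rule!r}")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class SurvivalParams:
    """Age-structured mortality-hazard model.

    ``beta0_A``: class intercepts (PB/SA/AD) on the log-hazard scale.
    ``beta_age``: per-age intercept adjustments (ages 1..25); the reference
    age of each class (1, 3, 5) is pinned to 0 for identifiability.
    ``beta_x_A``: (3, 8) covariate coefficients per class, columns in
    HAZARD_COVARIATES order.  ``Sigma_A``: 3x3 covariance of the yearly
    hazard deviations shared by all ages within a class.  ``upsilon_A``:
    lasso (double-exponential) scales for the covariate coefficients.
    """

    beta0_A: np.ndarray = field(default_factory=lambda: np.zeros(3))
    beta_age: np.ndarray = field(default_factory=lambda: np.zeros(MAX_AGE))
    beta_x_A: np.ndarray = field(default_factory=lambda: np.zeros((3, len(HAZARD_COVARIATES))))
    Sigma_A: np.ndarray = field(default_factory=lambda: 0.01 * np.eye(3))
    upsilon_A: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        self.beta0_A = np.asarray(self.beta0_A, float).reshape(3)
        self.beta_age = np.asarray(self.beta_age, float).reshape(MAX_AGE)
        self.beta_x_A = np.asarray(self.beta_x_A, float).reshape(3, len(HAZARD_COVARIATES))
        self.Sigma_A = np.asarray(self.Sigma_A, float).reshape(3, 3)
        self.upsilon_A = np.asarray(self.upsilon_A, float).reshape(3)


@dataclass
class MovementParams:
    F: float = 0.998
    psi: float = 0.984
    min_move_age: int = 4

    def __post_init__(self):
        if not (0.0 <= self.F <= 1.0 and 0.0 <= self.psi <= 1.0):
            raise ValueError("F and psi must lie in [0, 1]")


@dataclass
class DetectionParams:
    """Observation-process model.

    ``alpha_hat``: conditional breeding propensity for ages 2..6.
    ``p_mean``: logit-scale mean breeding detectability for (NC, VA);
    ``Sigma_p``: 2x2 covariance of yearly logit-detectability deviations;
    ``beta_p_band``: band-type adjustments (ancillary, PFR) on the logit scale.
    ``r_*``: dead-recovery model (intercept + env covariates + NC and band
    adjustments + yearly random effect sd).  ``R_*``: Florida non-breeding
    resight model, same layout.  ``rprime_rule``: mapping from R to R'.
    """

    alpha_hat: np.ndarray = field(default_factory=lambda: np.array([0.01, 0.08, 0.35, 0.70, 0.97]))
    p_mean: np.ndarray = field(default_factory=lambda: np.array([-6.9, -8.5]))
    Sigma_p: np.ndarray = field(default_factory=lambda: np.array([[2.23 ** 2, 0.5 * 2.23 * 4.82],
                                                                  [0.5 * 2.23 * 4.82, 4.82 ** 2]]))
    beta_p_band: np.ndarray = field(default_factory=lambda: np.array([0.13, 8.47]))
    r_intercept: float = -4.25
    r_beta_x: np.ndarray = field(default_factory=lambda: np.zeros(len(RECOVERY_COVARIATES)))
    r_beta_NC: float = 0.08
    r_beta_band: np.ndarray = field(default_factory=lambda: np.array([0.29, 0.36]))
    sigma_r: float = 0.28
    R_mean: float = -6.2
    R_beta_NC: float = 0.69
    R_beta_band: np.ndarray = field(default_factory=lambda: np.array([0.10, 2.24]))
    sigma_R: float = 1.59
    rprime_rule: str = "half"

    def __post_init__(self):
        self.alpha_hat = np.asarray(self.alpha_hat, float).reshape(5)
        if np.any(self.alpha_hat < 0) or np.any(self.alpha_hat > 1):
            raise ValueError("alpha_hat entries must lie in [0, 1]")
        self.p_mean = np.asarray(self.p_mean, float).reshape(2)
        self.Sigma_p = np.asarray(self.Sigma_p, float).reshape(2, 2)
        self.beta_p_band = np.asarray(self.beta_p_band, float).reshape(2)
        self.r_beta_x = np.asarray(self.r_beta_x, float).reshape(len(RECOVERY_COVARIATES))
        self.r_beta_band = np.asarray(self.r_beta_band, float).reshape(2)
        self.R_beta_band = np.asarray(self.R_beta_band, float).reshape(2)


@dataclass
class YearEffects:
    """Latent yearly deviations (fitted or simulated realizations)."""

    hazard: np.ndarray   # (n_years, 3) class-level hazard deviations
    u_r: np.ndarray      # (n_years,) recovery logit deviations
    u_R: np.ndarray      # (n_years,) non-breeding resight logit deviations
    u_p: np.ndarray      # (n_years, 2) breeding detectability logit deviations

    @classmethod
    def zeros(cls, n_years: int) -> "YearEffects":
        return cls(np.zeros((n_years, 3)), np.zeros(n_years),
                   np.zeros(n_years), np.zeros((n_years, 2)))


@dataclass
class DemographicParams:
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    movement: MovementParams = field(default_factory=MovementParams)
    detection: DetectionParams = field(default_factory=DetectionParams)


# ---------------------------------------------------------------------------
# covariates and realized per-year rates
# ---------------------------------------------------------------------------

def hazard_covariate_matrix(env: EnvSeries) -> np.ndarray:
    """(n_years, 8) z-scored covariate matrix in HAZARD_COVARIATES order.

    The series must be complete (imputed); z-constants come from observed
    cells so the scale does not drift across imputation draws.  Cached on
    the series object (fitting always hands over fresh completed copies).
    """
    cache = getattr(env, "_hazcache", None)
    if cache is None:
        sstz, _ = zstandardize(env.sst, env.sst_obs)
        hz, _ = harvest_z(env)
        fz = np.column_stack(
            [zstandardize(env.fish[:, i], env.fish_obs[:, i])[0] for i in range(3)]
        )
        hkz, _ = zstandardize(env.hooks, env.hooks_obs)
        cache = np.column_stack([sstz, hz, hkz, fz])
        env._hazcache = cache
    return cache


def hazard_linear(age: int, t: int, params: SurvivalParams, env: EnvSeries,
                  year_effect) -> float:
    """Log-hazard linear predictor for one age and year-index ``t`` (0-based).

    Ages above 25 share the oldest modelled age.  ``year_effect`` is the
    3-vector of class-level deviations for year ``t``.
    """
    a = min(int(age), MAX_AGE)
    if a < 1:
        raise ValueError("age must be >= 1")
    A = age_class(a)
    x = hazard_covariate_matrix(env)[t]
    return float(params.beta0_A[A] + params.beta_age[a - 1]
                 + params.beta_x_A[A] @ x + np.asarray(year_effect)[A])


@dataclass
class RealizedRates:
    """Per-(year, age, natal, band) probabilities implied by the parameters.

    ``S[a-1, t]`` is survival over the interval starting at year-index ``t``
    for a bird attaining age ``a`` at its end.  ``r/R/Rp[t, natal, band]``
    are interval quantities indexed by the interval's starting year; ``p[t,
    colony, band]`` is the occasion-t breeding detectability.  ``alpha[a]``
    is availability at age ``a`` (index 0 unused).
    """

    S: np.ndarray
    r: np.ndarray
    R: np.ndarray
    Rp: np.ndarray
    p: np.ndarray
    alpha: np.ndarray
    F: float
    psi: float
    min_move_age: int


def realized_rates(params: DemographicParams, env: EnvSeries,
                   effects: YearEffects) -> RealizedRates:
    """Expand coefficient-level parameters into per-year probabilities."""
    n = env.n_years
    sv, dt, mv = params.survival, params.detection, params.movement
    X = hazard_covariate_matrix(env)                       # (n, 8)

    eps = (sv.beta0_A[AGE_CLASS_OF][:, None]
           + sv.beta_age[:, None]
           + (X @ sv.beta_x_A.T).T[AGE_CLASS_OF]
           + effects.hazard.T[AGE_CLASS_OF])               # (25, n)
    S = survival_from_hazard(eps)

    Xr = X[:, [HAZARD_COVARIATES.index(c) for c in RECOVERY_COVARIATES]]
    logit_r = (dt.r_intercept + Xr @ dt.r_beta_x + effects.u_r)[:, None, None]
    logit_r = logit_r + np.array([dt.r_beta_NC, 0.0])[None, :, None]
    logit_r = logit_r + np.concatenate([[0.0], dt.r_beta_band])[None, None, :]
    r = _expit(logit_r)                                    # (n, natal, band)

    logit_R = (dt.R_mean + effects.u_R)[:, None, None]
    logit_R = logit_R + np.array([dt.R_beta_NC, 0.0])[None, :, None]
    logit_R = logit_R + np.concatenate([[0.0], dt.R_beta_band])[None, None, :]
    R = _expit(logit_R)
    Rp = rprime(R, dt.rprime_rule)

    logit_p = (dt.p_mean[None, :] + effects.u_p)[:, :, None]
    logit_p = logit_p + np.concatenate([[0.0], dt.beta_p_band])[None, None, :]
    p = _expit(logit_p)                                    # (n, colony, band)

    alpha = np.zeros(MAX_AGE + 1)
    for a in range(2, MAX_AGE + 1):
        alpha[a] = availability(a, dt.alpha_hat)
    return RealizedRates(S=S, r=r, R=R, Rp=Rp, p=p, alpha=alpha,
                         F=mv.F, psi=mv.psi, min_move_age=mv.min_move_age)


# ---------------------------------------------------------------------------
# transition / observation matrices
# ---------------------------------------------------------------------------

def build_transition(S, F, psi, r, move_allowed: bool = True) -> np.ndarray:
    """6x6 row-stochastic process matrix for one (interval, age) context.

    Live rows place ``S*F*psi`` on staying, ``S*F*(1-psi)`` on switching
    state, ``S*(1-F)`` on emigrating, and split mortality into recovered
    ``(1-S)*r`` (state 4) and unrecovered ``(1-S)*(1-r)`` (state 5).  Below
    the minimum breeding age movement is suppressed (``F = psi = 1``).
    """
    for v, lab in ((S, "S"), (F, "F"), (psi, "psi"), (r, "r")):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{lab} = {v} outside [0, 1]")
    if not move_allowed:
        F, psi = 1.0, 1.0
    P = np.zeros((N_STATES, N_STATES))
    for i in (0, 1):
        P[i, i] = S * F * psi
        P[i, 1 - i] = S * F * (1.0 - psi)
        P[i, 2] = S * (1.0 - F)
        P[i, 3] = (1.0 - S) * r
        P[i, 4] = (1.0 - S) * (1.0 - r)
    P[2, 2] = S
    P[2, 3] = (1.0 - S) * r
    P[2, 4] = (1.0 - S) * (1.0 - r)
    P[3, 5] = 1.0
    P[4, 5] = 1.0
    P[5, 5] = 1.0
    _check_rows(P, "process")
    return P


def build_observation(alpha, p_NC, p_VA, R, Rp) -> np.ndarray:
    """6x7 row-stochastic observation matrix for one (year, age) context.

    Emigrants (state 3) remain resightable in Florida and recoverable when
    dead -- emigration is defined only with respect to the mid-Atlantic
    breeding metapopulation.  State 4 emits the dead-recovery event with
    probability 1; state 5 emits the Florida-only event with probability
    ``R'``; state 6 is silent.
    """
    for v, lab in ((alpha, "alpha"), (p_NC, "p_NC"), (p_VA, "p_VA"), (R, "R"), (Rp, "R'")):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{lab} = {v} outside [0, 1]")
    O = np.zeros((N_STATES, N_EVENTS))
    for i, pd_ in ((0, alpha * p_NC), (1, alpha * p_VA)):
        O[i, i] = pd_ * R                # events 1 / 2 (breeding + FL)
        O[i, 2 + i] = pd_ * (1.0 - R)    # events 3 / 4 (breeding only)
        O[i, 4] = (1.0 - pd_) * R
        O[i, 5] = (1.0 - pd_) * (1.0 - R)
    O[2, 4] = R
    O[2, 5] = 1.0 - R
    O[3, 6] = 1.0
    O[4, 4] = Rp
    O[4, 5] = 1.0 - Rp
    O[5, 5] = 1.0
    _check_rows(O, "observation")
    return O


def _check_rows(M, label):
    if np.any(np.abs(M.sum(axis=1) - 1.0) > 1e-9):
        raise RuntimeError(f"{label} matrix rows do not sum to 1")


def build_matrices(rates: RealizedRates, n_years: int):
    """Stack process/observation matrices over (year, age, natal, band).

    ``Psi[t]`` governs the interval starting at year-index ``t`` (ages are
    the age *attained* at the interval's end); ``Omega[t]`` emits occasion
    ``t``'s event and uses the preceding interval's R and R'.
    """
    A = MAX_AGE
    Omega = np.zeros((n_years, A, 2, 3, N_STATES, N_EVENTS))
    S = rates.S                                     # (A, n)
    move = (np.arange(1, A + 1) >= rates.min_move_age)[:, None]  # (A, 1)
    F = np.where(move, rates.F, 1.0)
    psi = np.where(move, rates.psi, 1.0)
    r = rates.r                                     # (n, 2, 3)
    St = S.T[:, :, None, None]                      # (n, A, 1, 1)
    Ft = F.T[:, :, None, None] * np.ones_like(St)
    pst = psi.T[:, :, None, None] * np.ones_like(St)
    rt = r[:, None, :, :] * np.ones((1, A, 1, 1))   # (n, A, 2, 3)
    # natal axis of Psi only matters through r; broadcast to shape
    Psi = np.zeros((n_years, A, 2, 3, N_STATES, N_STATES))
    for i in (0, 1):
        Psi[..., i, i] = St * Ft * pst
        Psi[..., i, 1 - i] = St * Ft * (1.0 - pst)
        Psi[..., i, 2] = St * (1.0 - Ft)
        Psi[..., i, 3] = (1.0 - St) * rt
        Psi[..., i, 4] = (1.0 - St) * (1.0 - rt)
    Psi[..., 2, 2] = St
    Psi[..., 2, 3] = (1.0 - St) * rt
    Psi[..., 2, 4] = (1.0 - St) * (1.0 - rt)
    Psi[..., 3, 5] = 1.0
    Psi[..., 4, 5] = 1.0
    Psi[..., 5, 5] = 1.0

    alpha = rates.alpha[1:]                          # (A,) ages 1..25
    pN = rates.p[:, 0, :]                            # (n, band)
    pV = rates.p[:, 1, :]
    # R/R' of the interval preceding occasion t
    Rlag = np.empty_like(rates.R)
    Rlag[1:] = rates.R[:-1]
    Rlag[0] = rates.R[0]
    Rplag = np.empty_like(rates.Rp)
    Rplag[1:] = rates.Rp[:-1]
    Rplag[0] = rates.Rp[0]

    al = alpha[None, :, None, None]                  # (1, A, 1, 1)
    pNt = pN[:, None, None, :] * np.ones((1, A, 2, 1))
    pVt = pV[:, None, None, :] * np.ones((1, A, 2, 1))
    Rt = Rlag[:, None, :, :] * np.ones((1, A, 1, 1))
    Rpt = Rplag[:, None, :, :] * np.ones((1, A, 1, 1))
    dN = al * pNt
    dV = al * pVt
    Omega[..., 0, 0] = dN * Rt
    Omega[..., 0, 2] = dN * (1.0 - Rt)
    Omega[..., 0, 4] = (1.0 - dN) * Rt
    Omega[..., 0, 5] = (1.0 - dN) * (1.0 - Rt)
    Omega[..., 1, 1] = dV * Rt
    Omega[..., 1, 3] = dV * (1.0 - Rt)
    Omega[..., 1, 4] = (1.0 - dV) * Rt
    Omega[..., 1, 5] = (1.0 - dV) * (1.0 - Rt)
    Omega[..., 2, 4] = Rt
    Omega[..., 2, 5] = 1.0 - Rt
    Omega[..., 3, 6] = 1.0
    Omega[..., 4, 4] = Rpt
    Omega[..., 4, 5] = 1.0 - Rpt
    Omega[..., 5, 5] = 1.0
    return Psi, Omega


# ---------------------------------------------------------------------------
# encounter histories
# ---------------------------------------------------------------------------

@dataclass
class EncounterHistoryRecord:
    """One compressed cohort history.

    ``events[i]`` is the event code at the i-th study year; 0 before and at
    the release year (banding itself is not an event), 1-7 afterwards, and 0
    again after a dead-recovery (code 7).
    """

    release_year: int
    natal_state: str
    band_type: str
    events: np.ndarray
    count: int = 1

    def __post_init__(self):
        if self.natal_state not in NATAL_STATES:
            raise ValueError(f"unknown natal state {self.natal_state!r}")
        if self.band_type not in BAND_TYPES:
            raise ValueError(f"unknown band type {self.band_type!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        self.events = np.asarray(self.events, dtype=np.int8)

    def validate(self, years) -> None:
        years = np.asarray(years)
        rel = int(np.where(years == self.release_year)[0][0])
        ev = self.events
        if np.any(ev[: rel + 1] != 0):
            raise ValueError("events at or before release must be 0")
        rec = np.where(ev == 7)[0]
        if len(rec) > 1 or (len(rec) == 1 and np.any(ev[rec[0] + 1:] != 0)):
            raise ValueError("at most one dead recovery, then silence")
        tail = ev[rel + 1:]
        if len(rec) == 0 and np.any(tail == 0):
            raise ValueError("missing event codes after release")

    @property
    def key(self):
        return (self.release_year, self.natal_state, self.band_type,
                self.events.tobytes())


def compress_histories(records) -> list:
    """Merge identical (cohort, natal, band, events) histories, summing counts."""
    merged: dict = {}
    for rec in records:
        k = rec.key
        if k in merged:
            merged[k].count += rec.count
        else:
            merged[k] = EncounterHistoryRecord(rec.release_year, rec.natal_state,
                                               rec.band_type, rec.events.copy(),
                                               rec.count)
    return list(merged.values())


def histories_to_frame(records, years) -> pd.DataFrame:
    rows = [
        {
            "cohort_year": r.release_year,
            "natal_state": r.natal_state,
            "band_type": r.band_type,
            "event_string": "".join(str(int(e)) for e in r.events),
            "count": r.count,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def write_histories_csv(records, years, path) -> None:
    histories_to_frame(records, years).to_csv(path, index=False)


def read_histories_csv(path, years) -> list:
    df = pd.read_csv(path, dtype={"event_string": str})
    recs = []
    for _, row in df.iterrows():
        ev = np.array([int(c) for c in row["event_string"]], dtype=np.int8)
        rec = EncounterHistoryRecord(int(row["cohort_year"]), row["natal_state"],
                                     row["band_type"], ev, int(row["count"]))
        rec.validate(years)
        recs.append(rec)
    return recs


def write_histories_inp(records, years, path) -> None:
    """MARK-style .inp export: one semicolon-terminated row per history with
    one count column per natal-state x band-type group.

    The release occasion is marked with the digit 8 (our seven event codes
    plus a release marker do not fit MARK's two-character LDLD alphabet, so
    this is a multistate-coded variant; the CSV is the canonical format).
    """
    years = np.asarray(years)
    groups = [(s, b) for s in NATAL_STATES for b in BAND_TYPES]
    lines = [
        "/* columns: history ; counts per group "
        + " ".join(f"{s}-{b}" for s, b in groups) + " */"
    ]
    for rec in records:
        rel = int(np.where(years == rec.release_year)[0][0])
        chars = [str(int(e)) for e in rec.events]
        chars[rel] = "8"
        counts = [rec.count if (rec.natal_state, rec.band_type) == g else 0
                  for g in groups]
        lines.append("".join(chars) + " " + " ".join(str(c) for c in counts) + ";")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_histories_inp(path, years) -> list:
    years = np.asarray(years)
    groups = [(s, b) for s in NATAL_STATES for b in BAND_TYPES]
    recs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("/*"):
                continue
            body = line.rstrip(";").split()
            hist, counts = body[0], [int(c) for c in body[1:]]
            rel = hist.index("8")
            ev = np.array([0 if c == "8" else int(c) for c in hist], dtype=np.int8)
            for g, c in zip(groups, counts):
                if c > 0:
                    recs.append(EncounterHistoryRecord(int(years[rel]), g[0], g[1],
                                                       ev.copy(), c))
    return compress_histories(recs)


# ---------------------------------------------------------------------------
# marginalized likelihood
# ---------------------------------------------------------------------------

def _pack_records(records, years):
    years = np.asarray(years)
    year_of = {int(y): i for i, y in enumerate(years)}
    n = len(records)
    rel = np.empty(n, np.int64)
    natal = np.empty(n, np.int64)
    band = np.empty(n, np.int64)
    counts = np.empty(n, np.float64)
    events = np.zeros((n, len(years)), np.int64)
    for i, r in enumerate(records):
        rel[i] = year_of[int(r.release_year)]
        natal[i] = NATAL_STATES.index(r.natal_state)
        band[i] = BAND_TYPES.index(r.band_type)
        counts[i] = r.count
        events[i] = r.events
    return rel, natal, band, counts, events


@_njit(cache=False)
def _forward_kernel(rel, natal, band, events, Psi, Omega, T, out):  # pragma: no cover
    n = rel.shape[0]
    for i in range(n):
        v = np.zeros(N_STATES)
        v[natal[i]] = 1.0
        ll = 0.0
        for t in range(rel[i] + 1, T):
            e = events[i, t]
            a = t - rel[i]
            if a > MAX_AGE:
                a = MAX_AGE
            P = Psi[t - 1, a - 1, natal[i], band[i]]
            O = Omega[t, a - 1, natal[i], band[i]]
            w = np.zeros(N_STATES)
            tot = 0.0
            for s2 in range(N_STATES):
                acc = 0.0
                for s1 in range(N_STATES):
                    acc += v[s1] * P[s1, s2]
                acc *= O[s2, e - 1]
                w[s2] = acc
                tot += acc
            if tot <= 0.0:
                ll = -np.inf
                break
            ll += np.log(tot)
            for s2 in range(N_STATES):
                v[s2] = w[s2] / tot
            if e == 7:
                break
        out[i] = ll


def _forward_python(rel, natal, band, events, Psi, Omega, T, out):
    """Pure-numpy fallback for the compiled forward kernel."""
    for i in range(rel.shape[0]):
        v = np.zeros(N_STATES)
        v[natal[i]] = 1.0
        ll = 0.0
        for t in range(rel[i] + 1, T):
            e = events[i, t]
            a = min(t - rel[i], MAX_AGE)
            w = (v @ Psi[t - 1, a - 1, natal[i], band[i]]) * \
                Omega[t, a - 1, natal[i], band[i]][:, e - 1]
            tot = w.sum()
            if tot <= 0.0:
                ll = -np.inf
                break
            ll += math.log(tot)
            v = w / tot
            if e == 7:
                break
        out[i] = ll


def record_logliks(records, params: DemographicParams, env: EnvSeries,
                   effects: YearEffects | None = None,
                   packed=None) -> np.ndarray:
    """Per-record marginal log-likelihoods (count-unweighted).

    ``packed`` may carry the output of ``_pack_records`` to avoid re-packing
    an unchanged history set on every likelihood evaluation.
    """
    if effects is None:
        effects = YearEffects.zeros(env.n_years)
    rates = realized_rates(params, env, effects)
    Psi, Omega = build_matrices(rates, env.n_years)
    rel, natal, band, counts, events = packed or _pack_records(records, env.years)
    out = np.empty(len(records))
    kernel = _forward_kernel if _HAVE_NUMBA else _forward_python
    kernel(rel, natal, band, events, Psi, Omega, env.n_years, out)
    return out


def marginal_loglik(records, params: DemographicParams, env: EnvSeries,
                    effects: YearEffects | None = None, packed=None) -> float:
    """Count-weighted marginalized Barker log-likelihood of the history set.

    An event that is impossible under the parameters yields ``-inf`` with a
    diagnostic naming the first offending record.
    """
    lls = record_logliks(records, params, env, effects, packed=packed)
    if np.any(np.isneginf(lls)):
        i = int(np.where(np.isneginf(lls))[0][0])
        r = records[i]
        import warnings

        warnings.warn(
            "impossible encounter history under current parameters: "
            f"cohort {r.release_year} {r.natal_state}/{r.band_type} events "
            f"{''.join(str(int(e)) for e in r.events)}"
        )
        return -np.inf
    counts = np.array([r.count for r in records], float)
    return float(np.dot(counts, lls))


def write_loglik_diagnostics(records, params: DemographicParams, env: EnvSeries,
                             path, effects: YearEffects | None = None) -> "pd.DataFrame":
    """Per-record log-likelihood diagnostics table (written as CSV).

    Flags the records that contribute most to the deviance -- useful for
    spotting histories that the current parameters explain poorly.
    """
    lls = record_logliks(records, params, env, effects)
    df = histories_to_frame(records, env.years)
    df["loglik"] = lls
    df["count_weighted_loglik"] = lls * df["count"]
    df = df.sort_values("count_weighted_loglik").reset_index(drop=True)
    df.to_csv(path, index=False)
    return df


def brute_force_loglik(records, params: DemographicParams, env: EnvSeries,
                       effects: YearEffects | None = None,
                       max_occasions: int = 6) -> float:
    """Exact likelihood by enumerating every latent state sequence.

    Exponential cost; refuses more than ``max_occasions`` occasions.  Serves
    as the independent oracle for the forward algorithm.
    """
    if env.n_years > max_occasions:
        raise ValueError(f"brute force limited to {max_occasions} occasions")
    if effects is None:
        effects = YearEffects.zeros(env.n_years)
    rates = realized_rates(params, env, effects)
    Psi, Omega = build_matrices(rates, env.n_years)
    years = env.years
    total = 0.0
    for rec in records:
        rel = int(np.where(years == rec.release_year)[0][0])
        nat = NATAL_STATES.index(rec.natal_state)
        b = BAND_TYPES.index(rec.band_type)
        steps = []
        for t in range(rel + 1, env.n_years):
            e = int(rec.events[t])
            steps.append((t, e))
            if e == 7:
                break
        prob = 0.0
        for seq in _iproduct(range(N_STATES), repeat=len(steps)):
            p = 1.0
            prev = nat
            for (t, e), s in zip(steps, seq):
                a = min(t - rel, MAX_AGE)
                p *= Psi[t - 1, a - 1, nat, b][prev, s]
                p *= Omega[t, a - 1, nat, b][s, e - 1]
                if p == 0.0:
                    break
                prev = s
            prob += p
        total += rec.count * (math.log(prob) if prob > 0 else -np.inf)
    return float(total)
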