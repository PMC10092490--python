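"""Reproducible simulate -> fit -> summarize -> report pipeline.

Each stage reads/writes plain-text artifacts in a run directory, with the
resolved configuration frozen alongside them, so a run is self-describing
and exactly repeatable from its seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import barker, simulate as sim
from .barker import (
    AGE_CLASSES,
    HAZARD_COVARIATES,
    YearEffects,
    hazard_covariate_matrix,
    read_histories_csv,
    survival_from_hazard,
    write_histories_csv,
    write_histories_inp,
)
from .env import EnvSeries
from .inference import (
    CoefficientSummary,
    PosteriorDraws,
    hpdi,
    f_statistic,
    indirect_effect,
    rhat_table,
    standardize_latent_theoretic,
    survivorship_decline,
)
from .model import FitConfig, JointModel

log = logging.getLogger("ternpath")


@dataclass
class RunConfig:
    """Single configuration object driving all pipeline stages."""

    n_years: int = 30
    start_year: int = 1990
    per_year: int = 20000
    seed: int = sim.DEFAULT_SEED
    n_chains: int = 4
    n_iter: int = 2000
    n_burn: int = 2000
    thin: int = 1
    rprime_rule: str = "half"
    min_move_age: int = 4
    mode: str = "joint"
    free_adjust_ages: tuple = (2, 4)
    outdir: str = "runs/default"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "free_adjust_ages" in raw:
            raw["free_adjust_ages"] = tuple(raw["free_adjust_ages"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["free_adjust_ages"] = list(self.free_adjust_ages)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def fit_config(self) -> FitConfig:
        return FitConfig(n_chains=self.n_chains, n_iter=self.n_iter,
                         n_burn=self.n_burn, thin=self.thin, seed=self.seed,
                         rprime_rule=self.rprime_rule,
                         min_move_age=self.min_move_age,
                         free_adjust_ages=tuple(self.free_adjust_ages),
                         mode=self.mode)


def _content_hash(paths) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        with open(p, "rb") as fh:
            h.update(fh.read())
    return h.hexdigest()[:16]


def _ensure_outdir(outdir, force: bool):
    if os.path.exists(outdir) and os.listdir(outdir) and not force:
        raise FileExistsError(
            f"output directory {outdir!r} is not empty (use force=True)")
    os.makedirs(outdir, exist_ok=True)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def cmd_simulate(config: RunConfig, force: bool = False) -> dict:
    """Generate a synthetic study and write its file set."""
    t0 = time.time()
    _ensure_outdir(config.outdir, force)
    truth = sim.default_truth(n_years=config.n_years, start_year=config.start_year,
                              per_year=config.per_year, seed=config.seed)
    study = sim.simulate_study(truth)
    out = config.outdir
    paths = {
        "env": os.path.join(out, "env.csv"),
        "env_full": os.path.join(out, "env_full.csv"),
        "histories": os.path.join(out, "histories.csv"),
        "inp": os.path.join(out, "histories.inp"),
        "truth": os.path.join(out, "truth.json"),
        "config": os.path.join(out, "config.yaml"),
    }
    study.env.write_csv(paths["env"], blank_unobserved=True)
    study.env.write_csv(paths["env_full"], blank_unobserved=False)
    write_histories_csv(study.histories, study.env.years, paths["histories"])
    write_histories_inp(study.histories, study.env.years, paths["inp"])
    sim.truth_to_json(truth, paths["truth"])
    config.to_yaml(paths["config"])
    digest = _content_hash([paths[k] for k in ("env", "histories", "truth")])
    with open(os.path.join(out, "provenance.json"), "w") as fh:
        json.dump({"stage": "simulate", "seed": config.seed,
                   "content_hash": digest,
                   "n_records": len(study.histories),
                   "n_released": study.n_released,
                   "wall_s": round(time.time() - t0, 2)}, fh, indent=1)
    log.info("simulate: %d records from %d releases -> %s",
             len(study.histories), study.n_released, out)
    return paths


def cmd_fit(config: RunConfig, data_dir=None, seed=None) -> PosteriorDraws:
    """Fit the joint model to a run directory's data files."""
    t0 = time.time()
    data_dir = data_dir or config.outdir
    env = EnvSeries.read_csv(os.path.join(data_dir, "env.csv"))
    records = read_histories_csv(os.path.join(data_dir, "histories.csv"), env.years)
    rel_years = {r.release_year for r in records}
    if not rel_years.issubset(set(int(y) for y in env.years)):
        bad = sorted(rel_years - set(int(y) for y in env.years))
        raise ValueError(f"history release years not covered by env series: {bad}")
    model = JointModel(env, records, config.fit_config())
    draws = model.fit(seed=seed)
    prefix = os.path.join(data_dir, "draws")
    draws.save(prefix)
    with open(os.path.join(data_dir, "fit_log.json"), "w") as fh:
        json.dump({"stage": "fit", "seed": draws.seed,
                   "acceptance": draws.meta.get("acceptance", {}),
                   "n_records": len(records),
                   "wall_s": round(time.time() - t0, 2)}, fh, indent=1)
    log.info("fit: %d records, %.1fs -> %s.npz", len(records), time.time() - t0, prefix)
    return draws


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def band_ratio(coef_draws) -> dict:
    """Probability-scale band-effect ratio exp(beta).

    Emits both the posterior mean of exp(beta) and exp(posterior mean) --
    summaries of the ratio differ depending on which is taken, so both are
    reported.
    """
    x = np.ravel(np.asarray(coef_draws, float))
    return {"exp_mean_beta": float(np.exp(x.mean())),
            "mean_exp_beta": float(np.mean(np.exp(x)))}


def survival_profile_draws(draws: PosteriorDraws, env: EnvSeries,
                           config: FitConfig, ages=range(1, 6)) -> np.ndarray:
    """(n_draws, n_ages, n_years) age/year survival implied by the draws.

    The fitted model carries the yearly class-level log-hazards as absolute
    latent levels (``v_haz``); single-age intercept adjustments are added on
    top.
    """
    v = draws.flat("v_haz").reshape(-1, env.n_years, 3) \
        + draws.flat("haz_level")[:, None, :]
    n_draws = v.shape[0]
    beta_age = np.zeros((n_draws, barker.MAX_AGE))
    if config.free_adjust_ages and "haz_beta_age" in draws.names:
        ba = draws.flat("haz_beta_age")
        for i, a in enumerate(config.free_adjust_ages):
            beta_age[:, a - 1] = ba[:, i]
    ages = np.asarray(list(ages), int)
    Acls = barker.AGE_CLASS_OF[ages - 1]
    eps = (np.transpose(v, (0, 2, 1))[:, Acls, :]
           + beta_age[:, ages - 1][:, :, None])
    return survival_from_hazard(eps)


def summarize_parameters(draws: PosteriorDraws, names=None) -> pd.DataFrame:
    rows = []
    for name in (names or draws.names):
        v = draws.flat(name)
        v2 = v.reshape(v.shape[0], -1)
        for j in range(v2.shape[1]):
            lab = name if v2.shape[1] == 1 else f"{name}[{j}]"
            s = CoefficientSummary.from_draws(lab, v2[:, j])
            rows.append({"parameter": lab, "mean": s.mean,
                         "hpdi90_lo": s.hpdi90[0], "hpdi90_hi": s.hpdi90[1],
                         "f": s.f})
    return pd.DataFrame(rows)


def cmd_report(config: RunConfig, data_dir=None) -> dict:
    """Summaries, convergence table, band ratios, derived quantities."""
    data_dir = data_dir or config.outdir
    draws = PosteriorDraws.load(os.path.join(data_dir, "draws"))
    env = EnvSeries.read_csv(os.path.join(data_dir, "env.csv"))
    fitcfg = config.fit_config()

    report: dict = {}
    # convergence on structural (non-latent) parameters
    structural = [n for n in draws.names
                  if n not in ("rho", "env_missing", "v_haz", "haz_level",
                               "v_p", "v_r", "v_R")]
    rt = rhat_table(draws, structural)
    report["rhat_max"] = max(rt["rhat"].values())
    report["rhat_flagged"] = rt["flagged"]

    summary = summarize_parameters(draws, structural)
    summary.to_csv(os.path.join(data_dir, "summary.csv"), index=False)
    report["summary"] = summary

    # band-effect probability ratios
    ratios = {}
    for nm, lab in (("r_band", "recovery"), ("R_band", "nonbreeding_resight"),
                    ("p_band", "breeding_detection")):
        if nm in draws.names:
            v = draws.flat(nm)
            for j, btype in enumerate(("ancillary", "PFR")):
                ratios[f"{lab}_{btype}"] = band_ratio(v[:, j])
    report["band_ratios"] = ratios

    # derived demographic quantities
    derived = {}
    if "v_haz" in draws.names:
        S = survival_profile_draws(draws, env, fitcfg)     # (d, 5, n)
        Sbar = S.mean(axis=2)
        for i, a in enumerate(range(1, 6)):
            derived[f"S_age{a}_mean"] = float(Sbar[:, i].mean())
        half = env.n_years // 2
        blocks = [list(range(half)), list(range(half, env.n_years))]
        c1 = np.prod(S[:, :, blocks[0]].mean(axis=2), axis=1)
        c2 = np.prod(S[:, :, blocks[1]].mean(axis=2), axis=1)
        derived["cumulative_period1"] = float(c1.mean())
        derived["cumulative_period2"] = float(c2.mean())
        decline = 1.0 - c2 / c1
        derived["prerecruitment_decline"] = float(decline.mean())
        derived["prerecruitment_decline_hpdi90"] = list(hpdi(decline))
        if "alpha" in draws.names:
            al = draws.flat("alpha")
            for j, a in enumerate(range(2, 7)):
                derived[f"alpha_age{a}_mean"] = float(al[:, j].mean())
    report["derived"] = derived

    # standardized direct + indirect path effects (correlation scale)
    paths = {}
    if "v_haz" in draws.names and "fish_MN_beta" in draws.names:
        from ternpath.barker import HAZARD_COVARIATES
        X = hazard_covariate_matrix(env)
        sd_mn = float(np.std(env.fish[env.fish_obs[:, 0], 0]))
        hz_tr = X[:, HAZARD_COVARIATES.index("TR")]
        # trawl -> menhaden (identity link): beta * sd_x / sd_y
        b_tr_mn = draws.flat("fish_MN_beta")[:, 4]
        rho_tr_mn = standardize_latent_theoretic(
            b_tr_mn, "identity", float(np.std(hz_tr)), sd_mn)
        # menhaden -> adult mortality (log-log link): latent-theoretic
        bx = draws.flat("haz_beta_x").reshape(-1, 3, len(HAZARD_COVARIATES))
        b_mn_ad = bx[:, 2, HAZARD_COVARIATES.index("MN")]
        v_ad = draws.flat("v_haz").reshape(-1, env.n_years, 3)[:, :, 2] \
            + draws.flat("haz_level")[:, 2][:, None]
        sd_lp = np.std(v_ad, axis=1)
        mnz = X[:, HAZARD_COVARIATES.index("MN")]
        rho_mn_ad = standardize_latent_theoretic(b_mn_ad, "loglog",
                                                 float(np.std(mnz)), sd_lp)
        eff = indirect_effect({"TR->MN": rho_tr_mn, "MN->AD_mortality": rho_mn_ad},
                              ["TR->MN", "MN->AD_mortality"])
        paths["TR->MN->AD_mortality"] = {
            "mean": eff.summary.mean, "hpdi90": list(eff.summary.hpdi90),
            "f": eff.summary.f,
            "edges": {"TR->MN": float(np.mean(rho_tr_mn)),
                      "MN->AD_mortality": float(np.mean(rho_mn_ad))},
        }
    report["path_effects"] = paths

    with open(os.path.join(data_dir, "report.json"), "w") as fh:
        json.dump({k: v for k, v in report.items() if k != "summary"},
                  fh, indent=1, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


# ---------------------------------------------------------------------------
# quick self-checks ("validate" stage)
# ---------------------------------------------------------------------------

def validate(seed: int = 0, n_instances: int = 50) -> dict:
    """Fast oracle/property sweep: forward vs brute-force likelihood on random
    small instances, matrix row sums, and m-array closure on a toy scenario."""
    from .simulate import default_truth, gen_environment, expected_marray
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        env, records, params, effects = _random_small_instance(rng)
        a = barker.marginal_loglik(records, params, env, effects)
        b = barker.brute_force_loglik(records, params, env, effects)
        if np.isfinite(a) or np.isfinite(b):
            worst = max(worst, abs(a - b))
    truth = default_truth(n_years=6, per_year=200, seed=seed + 1)
    truth.missing = {}
    env = gen_environment(truth)
    ma = expected_marray(truth, env)
    closure = float(np.max(np.abs(
        ma.groupby(["cohort_year", "natal_state", "band_type"])["expected"].sum()
        - truth.releases.groupby(["year", "natal_state", "band_type"])["n"].sum().values
    )))
    return {"forward_vs_brute_max_abs": worst, "marray_closure_max_abs": closure}


def _random_small_instance(rng, n_years: int = 4):
    """A tiny random parameterization + histories for oracle checks."""
    from .simulate import default_truth

    truth = default_truth(n_years=n_years, per_year=10, seed=int(rng.integers(2 ** 31)))
    truth.missing = {}
    env = sim.gen_environment(truth, int(rng.integers(2 ** 31)))
    demo = truth.demo_params
    # scramble the key probabilities so the sweep explores parameter space
    demo.movement.F = rng.uniform(0.5, 1.0)
    demo.movement.psi = rng.uniform(0.5, 1.0)
    demo.movement.min_move_age = int(rng.integers(1, 5))
    demo.detection.alpha_hat = rng.uniform(0, 1, 5)
    demo.detection.p_mean = rng.normal(-1.5, 1.0, 2)
    demo.detection.r_intercept = float(rng.normal(-2.0, 0.7))
    demo.detection.R_mean = float(rng.normal(-2.0, 0.7))
    demo.detection.rprime_rule = "half" if rng.random() < 0.5 else "square"
    demo.survival.beta0_A = rng.normal(-0.3, 0.7, 3)
    study = sim.gen_histories(truth, env, int(rng.integers(2 ** 31)))
    records = study.histories
    return env, records, demo, study.effects
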