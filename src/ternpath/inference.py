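"""Posterior computation: sampler and summary calculus.

The sampler is a blocked adaptive random-walk Metropolis-within-Gibbs: the
parameter vector is partitioned into blocks, each updated with a Gaussian
random-walk proposal whose scale adapts toward a target acceptance rate
(0.44 for scalar blocks, 0.234 otherwise) and whose shape adapts to the
running empirical covariance of the block during burn-in.  The log-posterior
is supplied as named *terms*; each block declares which terms it touches, so
updating a cheap block (say, an environmental regression) never re-evaluates
the expensive demographic likelihood.

Summary operations mirror the source analysis: proportion of posterior mass
on the mean's side of zero (``f``), shortest-interval HPDIs, latent-theoretic
standardization of link-scale coefficients to correlation-scale ``rho``,
per-draw products for indirect path effects, cumulative pre-recruitment
survivorship, and the classic Gelman-Rubin potential scale reduction factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

_LOGIT_RESID_VAR = np.pi ** 2 / 3.0   # logistic latent-residual variance
_LOGLOG_RESID_VAR = np.pi ** 2 / 6.0  # Gumbel latent-residual variance


# ---------------------------------------------------------------------------
# draws container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Labeled MCMC draws: each name maps to (chains, iterations, *shape)."""

    draws: dict
    seed: int | None = None
    n_burn: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {k: v.shape[:2] for k, v in self.draws.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError("all parameters need equal (chains, iterations)")

    @property
    def names(self):
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_iter(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def get(self, name: str) -> np.ndarray:
        return self.draws[name]

    def flat(self, name: str) -> np.ndarray:
        """Concatenate chains: (chains*iterations, *shape)."""
        v = self.draws[name]
        return v.reshape(-1, *v.shape[2:])

    def save(self, prefix) -> None:
        np.savez_compressed(f"{prefix}.npz", **self.draws)
        manifest = {
            "seed": self.seed,
            "n_burn": self.n_burn,
            "n_chains": self.n_chains,
            "n_iter": self.n_iter,
            "parameters": {k: list(v.shape[2:]) for k, v in self.draws.items()},
            "meta": self.meta,
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, prefix) -> "PosteriorDraws":
        with open(f"{prefix}.json") as fh:
            manifest = json.load(fh)
        with np.load(f"{prefix}.npz") as z:
            draws = {k: z[k] for k in z.files}
        return cls(draws=draws, seed=manifest.get("seed"),
                   n_burn=manifest.get("n_burn", 0), meta=manifest.get("meta", {}))


# ---------------------------------------------------------------------------
# blocked adaptive Metropolis
# ---------------------------------------------------------------------------

@dataclass
class Block:
    """One update block: parameter indices and the posterior terms it moves.

    ``init_chol`` optionally seeds the proposal shape (e.g. with the Cholesky
    factor of a least-squares coefficient covariance) so that strongly
    correlated coordinates -- collinear regression designs in particular --
    are proposed along their ridge from the first iteration; the adaptive
    covariance then refines it.
    """

    name: str
    idx: np.ndarray
    terms: tuple
    scale: float = 0.1
    init_chol: np.ndarray | None = None
    #: optional exact conditional sampler ``gibbs(theta, rng) -> new subvector``;
    #: when set, the block is updated by direct draws instead of Metropolis
    gibbs: object = None
    #: update the block only every k-th scan (valid systematic-scan kernel);
    #: used for expensive blocks whose mixing is not rate-limiting
    every: int = 1
    #: optional (len(idx), m) move matrix: proposals are scale * move @ z with
    #: z ~ N(0, I_m).  Used for low-dimensional coherent moves (e.g. shifting
    #: a whole latent family along a posterior ridge); only the scale adapts.
    move: np.ndarray | None = None

    def __post_init__(self):
        self.idx = np.asarray(self.idx, dtype=int)


class SamplerError(RuntimeError):
    pass


def _target_rate(dim: int) -> float:
    return 0.44 if dim == 1 else 0.234


def run_sampler(terms: dict, blocks: list, init: np.ndarray, n_chains: int = 4,
                n_iter: int = 2000, n_burn: int = 1000, seed: int = 0,
                thin: int = 1, init_jitter: float = 0.02):
    """Sample the log-posterior ``sum(terms.values())`` with blocked adaptive
    random-walk Metropolis.

    Returns ``(samples, info)`` with ``samples`` of shape
    ``(n_chains, n_iter//thin, d)`` (post-burn-in) and per-block acceptance
    rates in ``info``.  Deterministic under a fixed seed.  Raises
    ``SamplerError`` with a parameter dump if the initial point has a
    non-finite log-posterior.
    """
    init = np.asarray(init, dtype=float)
    d = init.size
    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(n_chains)
    n_keep = n_iter // thin
    samples = np.empty((n_chains, n_keep, d))
    acc = {b.name: np.zeros(n_chains) for b in blocks}

    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        vals = None
        for attempt in range(100):  # a jitter draw may cross a support boundary
            scale = init_jitter * 0.5 ** (attempt // 10)
            theta = init + scale * rng.standard_normal(d)
            vals = {k: f(theta) for k, f in terms.items()}
            if np.all(np.isfinite(list(vals.values()))):
                break
        else:
            bad = {k: v for k, v in vals.items() if not np.isfinite(v)}
            raise SamplerError(
                f"non-finite log-posterior at init: {bad}; theta={theta!r}")
        scales = {b.name: b.scale for b in blocks}
        chol = {b.name: (None if b.init_chol is None else b.init_chol.copy())
                for b in blocks}
        hist = {b.name: [] for b in blocks}
        n_prop = {b.name: 0 for b in blocks}
        n_acc = {b.name: 0 for b in blocks}

        kept = 0
        for it in range(n_burn + n_iter):
            for b in blocks:
                if b.every > 1 and it % b.every:
                    continue
                if b.gibbs is not None:
                    theta = theta.copy()
                    theta[b.idx] = b.gibbs(theta, rng)
                    for t in b.terms:
                        vals[t] = terms[t](theta)
                    n_prop[b.name] += 1
                    n_acc[b.name] += 1
                    continue
                if b.move is not None:
                    k = b.move.shape[1]
                    step = scales[b.name] * (b.move @ rng.standard_normal(k))
                else:
                    k = b.idx.size
                    z = rng.standard_normal(k)
                    step = scales[b.name] * (z if chol[b.name] is None else chol[b.name] @ z)
                prop = theta.copy()
                prop[b.idx] += step
                new_vals = {}
                delta = 0.0
                ok = True
                for t in b.terms:
                    nv = terms[t](prop)
                    new_vals[t] = nv
                    if not np.isfinite(nv) and nv != -np.inf:
                        ok = False
                        break
                    delta += nv - vals[t]
                n_prop[b.name] += 1
                if ok and np.log(rng.random()) < delta:
                    theta = prop
                    vals.update(new_vals)
                    n_acc[b.name] += 1
                    accepted = True
                else:
                    accepted = False
                if it < n_burn:
                    # Robbins-Monro scale adaptation + covariance shaping
                    rate = 1.0 if accepted else 0.0
                    gamma = min(0.25, 5.0 / (1.0 + it))
                    scales[b.name] *= np.exp(gamma * (rate - _target_rate(k)))
                    hist[b.name].append(theta[b.idx].copy())
                    if k > 1 and it >= 100 and it % 50 == 0:
                        H = np.asarray(hist[b.name][len(hist[b.name]) // 3:])
                        if H.shape[0] > 2 * k:
                            cov = np.cov(H.T) + 1e-8 * np.eye(k)
                            try:
                                chol[b.name] = np.linalg.cholesky(cov / np.trace(cov) * k)
                            except np.linalg.LinAlgError:
                                pass
            if it >= n_burn and (it - n_burn) % thin == 0:
                samples[c, kept] = theta
                kept += 1
        for b in blocks:
            acc[b.name][c] = n_acc[b.name] / max(1, n_prop[b.name])
    info = {"acceptance": {k: v.copy() for k, v in acc.items()},
            "seed": seed, "n_burn": n_burn, "n_iter": n_iter}
    return samples, info


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def f_statistic(x) -> float:
    """Proportion of draws on the same side of zero as the posterior mean
    (0.5 by convention when the mean is exactly zero)."""
    x = np.ravel(np.asarray(x, dtype=float))
    if x.size < 2:
        raise ValueError("need at least 2 draws")
    m = x.mean()
    if m == 0.0:
        return 0.5
    s = np.sign(m)
    return float(np.mean(np.sign(x) == s) + 0.5 * np.mean(x == 0.0))


def hpdi(x, prob: float = 0.90) -> tuple:
    """Shortest interval containing ``prob`` posterior mass."""
    x = np.sort(np.ravel(np.asarray(x, dtype=float)))
    n = x.size
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


@dataclass
class CoefficientSummary:
    name: str
    mean: float
    hpdi90: tuple
    f: float
    rho: float | None = None
    hpdi95: tuple | None = None

    @classmethod
    def from_draws(cls, name, x, rho_draws=None) -> "CoefficientSummary":
        x = np.ravel(np.asarray(x, float))
        return cls(name=name, mean=float(x.mean()), hpdi90=hpdi(x, 0.90),
                   f=f_statistic(x),
                   rho=None if rho_draws is None else float(np.mean(rho_draws)),
                   hpdi95=hpdi(x, 0.95))


def standardize_latent_theoretic(beta, link: str, sd_x, sd_y_or_latent):
    """Convert a link-scale slope to a correlation-scale coefficient.

    identity: ``rho = beta * sd_x / sd_y``.  For binary-response links the
    denominator is the latent-response sd: sqrt(linear-predictor variance +
    link residual variance), with residual variance pi^2/3 (logit) or pi^2/6
    (log-log / Gumbel); ``sd_y_or_latent`` is then the linear-predictor sd.
    """
    beta = np.asarray(beta, dtype=float)
    sd_x = float(sd_x)
    if sd_x <= 0:
        raise ValueError("sd_x must be positive")
    s = np.asarray(sd_y_or_latent, dtype=float)
    if link == "identity":
        return beta * sd_x / s
    if link == "logit":
        return beta * sd_x / np.sqrt(s ** 2 + _LOGIT_RESID_VAR)
    if link == "loglog":
        return beta * sd_x / np.sqrt(s ** 2 + _LOGLOG_RESID_VAR)
    raise ValueError(f"unknown link {link!r}")


@dataclass
class PathEffect:
    """Indirect effect along an ordered chain of standardized edges."""

    edges: tuple
    product_draws: np.ndarray
    summary: CoefficientSummary

    @classmethod
    def from_draws(cls, draws: dict, edges) -> "PathEffect":
        edges = tuple(edges)
        if len(edges) < 2:
            raise ValueError("a path needs at least 2 edges")
        missing = [e for e in edges if e not in draws]
        if missing:
            raise KeyError(f"missing edge coefficients: {missing}")
        prod = np.ones_like(np.ravel(np.asarray(draws[edges[0]], float)))
        for e in edges:
            prod = prod * np.ravel(np.asarray(draws[e], float))
        name = " -> ".join(edges)
        return cls(edges=edges, product_draws=prod,
                   summary=CoefficientSummary.from_draws(name, prod))


def indirect_effect(draws: dict, edges) -> PathEffect:
    """Per-draw product of edge coefficients, then summarized (never the
    product of the summaries)."""
    return PathEffect.from_draws(draws, edges)


def cumulative_survival(S_draws, ages, year_blocks=None, years=None):
    """Cumulative pre-recruitment survivorship and its between-period decline.

    ``S_draws``: (n_draws, n_ages, n_years) age- by year-specific survival,
    or (n_draws, n_ages) period means.  Per draw the survival of each age is
    averaged within each year block, the within-block means are multiplied
    across ``ages``, and the relative decline ``1 - c2/c1`` between the first
    and second block is formed.  Returns a dict of draw vectors.
    """
    S = np.asarray(S_draws, dtype=float)
    ages = np.asarray(ages, int)
    if np.any(np.diff(ages) != 1) or ages[0] != 1:
        raise ValueError("ages must be contiguous from 1")
    if S.ndim == 2:
        S = S[:, :, None]
        year_blocks = [[0]]
        cum = [np.prod(S[:, ages - 1, 0], axis=1)]
    else:
        if year_blocks is None:
            raise ValueError("year_blocks required for year-resolved draws")
        cum = []
        for block in year_blocks:
            block = np.asarray(block, int)
            Sbar = S[:, :, :][:, ages - 1][:, :, block].mean(axis=2)
            cum.append(np.prod(Sbar, axis=1))
    out = {f"cumulative_period{i + 1}": c for i, c in enumerate(cum)}
    if len(cum) >= 2:
        out["decline"] = 1.0 - cum[1] / cum[0]
    return out


def survivorship_decline(period1_mean, period2_mean) -> float:
    """Relative decline ``1 - c2/c1`` between two period survivorships."""
    return float(1.0 - np.asarray(period2_mean, float) / np.asarray(period1_mean, float))


def rhat(x) -> float:
    """Classic Gelman-Rubin potential scale reduction for one parameter,
    from draws shaped (chains, iterations)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need (chains >= 2, iterations) draws")
    m, n = x.shape
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    if W == 0:
        return 1.0
    return float(np.sqrt(var_plus / W))


def rhat_table(draws: PosteriorDraws, names=None, threshold: float = 1.1) -> dict:
    """R-hat per (scalar element of each) parameter; flags values above the
    convergence threshold."""
    out = {}
    for name in (names or draws.names):
        v = draws.get(name)
        flatdim = int(np.prod(v.shape[2:])) if v.ndim > 2 else 1
        vv = v.reshape(v.shape[0], v.shape[1], flatdim)
        for j in range(flatdim):
            label = name if flatdim == 1 else f"{name}[{j}]"
            out[label] = rhat(vv[:, :, j])
    flagged = {k: v for k, v in out.items() if v > threshold}
    return {"rhat": out, "flagged": flagged}
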