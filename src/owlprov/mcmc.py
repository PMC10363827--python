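"""Posterior sampling, convergence diagnostics, and the credible-interval
significance rules shared by every model in the package.

The sampler is an adaptive random-walk Metropolis-within-Gibbs: the
models here are low-dimensional (a handful of fixed effects plus grouped
random effects), so a robust gradient-free sampler with per-parameter
proposal scales tuned during burn-in is sufficient and dependency-light.
Bounded parameters (uniform or half-normal priors) are proposed with
reflection at the support boundary, which preserves detailed balance.

Inference decisions downstream use two rules: a slope is significant when
its 95% CRI excludes zero, and two groups differ significantly when their
95% CRIs do not overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ChainConfig",
    "Uniform",
    "Normal",
    "HalfNormal",
    "Flat",
    "PriorSpec",
    "ParamSummary",
    "PosteriorSummary",
    "sample_posterior",
    "rhat",
    "credible_interval",
    "intervals_overlap",
    "pearson_residuals",
]

RHAT_WARN = 1.1  # convergence threshold: R-hat below this is acceptable


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run configuration.

    ``n_iterations`` counts post-initialization sweeps per chain including
    burn-in; draws kept are the post-burn-in sweeps thinned by ``thin``.
    """

    n_iterations: int
    n_burnin: int
    n_chains: int = 3
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be < n_iterations")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for R-hat")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def scaled(self, factor: float) -> "ChainConfig":
        """A proportionally shorter (or longer) run with the same seed."""
        return ChainConfig(
            n_iterations=max(20, int(self.n_iterations * factor)),
            n_burnin=max(10, int(self.n_burnin * factor)),
            n_chains=self.n_chains,
            thin=self.thin,
            seed=self.seed,
        )


# --- priors ----------------------------------------------------------------

class Prior:
    """Base class: unnormalized log-density plus support and a start point."""

    bounds: tuple[float, float] = (-math.inf, math.inf)

    def logpdf(self, x: float) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def start(self) -> float:
        raise NotImplementedError

    def start_scale(self) -> float:
        raise NotImplementedError


@dataclass(frozen=True)
class Uniform(Prior):
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("uniform prior needs lo < hi")
        object.__setattr__(self, "bounds", (self.lo, self.hi))

    def logpdf(self, x: float) -> float:
        return 0.0 if self.lo <= x <= self.hi else -math.inf

    def start(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def start_scale(self) -> float:
        return 0.1 * (self.hi - self.lo)


@dataclass(frozen=True)
class Normal(Prior):
    """Normal prior parameterized by mean and *variance* (not sd)."""

    mean: float = 0.0
    variance: float = 1000.0

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError("variance must be > 0")

    def logpdf(self, x: float) -> float:
        return -0.5 * (x - self.mean) ** 2 / self.variance

    def start(self) -> float:
        return self.mean

    def start_scale(self) -> float:
        # wide priors should not inflate the initial proposal scale
        return min(math.sqrt(self.variance), 1.0)


@dataclass(frozen=True)
class HalfNormal(Prior):
    """Half-normal prior on [0, inf) with the given scale (sd of the full
    normal); used for standard-deviation parameters."""

    scale: float = 1.0
    bounds = (0.0, math.inf)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be > 0")
        object.__setattr__(self, "bounds", (0.0, math.inf))

    def logpdf(self, x: float) -> float:
        return -0.5 * x * x / (self.scale * self.scale) if x >= 0 else -math.inf

    def start(self) -> float:
        return 0.5 * self.scale

    def start_scale(self) -> float:
        return min(0.5 * self.scale, 1.0)


@dataclass(frozen=True)
class Flat(Prior):
    """Improper flat prior: used for parameters (e.g. random effects)
    whose distribution is part of the model's own log-density."""

    init: float = 0.0
    scale: float = 1.0

    def logpdf(self, x: float) -> float:
        return 0.0

    def start(self) -> float:
        return self.init

    def start_scale(self) -> float:
        return self.scale


PriorSpec = Mapping[str, Prior]


# --- summaries -------------------------------------------------------------

@dataclass(frozen=True)
class ParamSummary:
    mean: float
    cri_lo: float
    cri_hi: float
    rhat: float

    @property
    def cri(self) -> tuple[float, float]:
        return (self.cri_lo, self.cri_hi)


@dataclass
class PosteriorSummary:
    """Per-parameter posterior means, 95% CRIs and R-hat, plus the retained
    draws (chains x draws) for downstream posterior functionals."""

    params: dict[str, ParamSummary]
    draws: dict[str, np.ndarray]
    warnings: list[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> ParamSummary:
        return self.params[name]

    def flat(self, name: str) -> np.ndarray:
        """All post-burn-in draws of one parameter, chains concatenated."""
        return self.draws[name].reshape(-1)

    def cri(self, name: str) -> tuple[float, float]:
        return self.params[name].cri

    @property
    def converged(self) -> bool:
        return all(p.rhat < RHAT_WARN for p in self.params.values()
                   if np.isfinite(p.rhat))

    def to_dict(self) -> dict:
        d = {name: {"mean": p.mean, "cri_lo": p.cri_lo, "cri_hi": p.cri_hi,
                    "rhat": p.rhat}
             for name, p in self.params.items()}
        return {"params": d, "warnings": list(self.warnings)}

    def draws_frame(self):
        """Long-format draws table (chain, iteration, parameter, value),
        suitable for CSV persistence and external diagnostics."""
        import pandas as pd

        frames = []
        for name, arr in self.draws.items():
            m, n = arr.shape
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(m), n),
                "iteration": np.tile(np.arange(n), m),
                "parameter": name,
                "value": arr.reshape(-1),
            }))
        return pd.concat(frames, ignore_index=True)


def summarize_draws(draws: dict[str, np.ndarray],
                    level: float = 0.95) -> PosteriorSummary:
    """Build a :class:`PosteriorSummary` from per-parameter (chains, n)
    draw arrays, computing means, equal-tailed CRIs and R-hat."""
    params = {}
    warnings: list[str] = []
    for name, arr in draws.items():
        flat = arr.reshape(-1)
        lo, hi = credible_interval(flat, level)
        try:
            r = rhat(arr)
        except ValueError:
            r = 1.0 if np.ptp(flat) == 0 else math.inf
        if r >= RHAT_WARN:
            warnings.append(f"R-hat {r:.3f} >= {RHAT_WARN} for {name}")
        params[name] = ParamSummary(float(flat.mean()), lo, hi, float(r))
    return PosteriorSummary(params=params, draws=draws, warnings=warnings)


# --- sampler ---------------------------------------------------------------

def _reflect(x: float, lo: float, hi: float) -> float:
    # fold a proposal into [lo, hi] by reflection (exact, any distance);
    # preserves proposal symmetry so no Hastings correction is needed
    if lo == -math.inf and hi == math.inf:
        return x
    if hi == math.inf:
        return lo + abs(x - lo)
    if lo == -math.inf:
        return hi - abs(hi - x)
    width = hi - lo
    if width <= 0:
        return lo
    z = math.fmod(x - lo, 2.0 * width)
    if z < 0:
        z += 2.0 * width
    return lo + (z if z <= width else 2.0 * width - z)


def sample_posterior(
    log_density: Callable[[np.ndarray], float],
    priors: PriorSpec,
    config: ChainConfig,
    level: float = 0.95,
    starts: Mapping[str, float] | None = None,
) -> PosteriorSummary:
    """Sample the posterior of ``log_density(theta) + log prior(theta)``.

    Parameters
    ----------
    log_density:
        Log-likelihood (or likelihood plus hierarchical terms) as a
        function of the parameter vector, ordered as ``priors`` iterates.
        Must be finite at an interior start point of the prior support.
    priors:
        Ordered mapping parameter name -> :class:`Prior`.
    config:
        Chain configuration; the run is reproducible bit-for-bit given
        (priors, data, config) since all chains draw from generators
        seeded deterministically from ``config.seed``.
    starts:
        Optional data-driven start values per parameter (e.g. crude
        method-of-moments estimates); chains still start overdispersed
        around them.  Parameters not listed start at the prior's start
        point.

    Returns
    -------
    PosteriorSummary
        Posterior means, 95% equal-tailed CRIs, per-parameter R-hat, and
        the retained draws.  An R-hat at or above 1.1 adds a convergence
        warning to the summary; it never raises.

    Raises
    ------
    RuntimeError
        If no chain can find a finite-density start point.
    """
    names = list(priors.keys())
    prior_list = [priors[n] for n in names]
    p = len(names)
    n_keep = (config.n_iterations - config.n_burnin) // config.thin
    draws = {n: np.empty((config.n_chains, n_keep)) for n in names}

    base_start = np.array(
        [starts.get(n, priors[n].start()) if starts else priors[n].start()
         for n in names], dtype=float)
    for i, pr in enumerate(prior_list):
        lo, hi = pr.bounds
        base_start[i] = _reflect(base_start[i], lo, hi)

    for chain in range(config.n_chains):
        rng = np.random.default_rng([int(config.seed) % (2**31), chain])
        theta = base_start.copy()
        scales = np.array([max(pr.start_scale(), 1e-8) for pr in prior_list],
                          dtype=float)
        # overdispersed start: jitter within the support
        for i, pr in enumerate(prior_list):
            lo, hi = pr.bounds
            theta[i] = _reflect(theta[i] + scales[i] * rng.standard_normal(), lo, hi)
        logprior = sum(pr.logpdf(theta[i]) for i, pr in enumerate(prior_list))
        logpost = log_density(theta) + logprior
        if not np.isfinite(logpost):
            theta = base_start.copy()
            logprior = sum(pr.logpdf(theta[i]) for i, pr in enumerate(prior_list))
            logpost = log_density(theta) + logprior
        if not np.isfinite(logpost):
            raise RuntimeError("log density not finite at the prior start point")

        accepted = np.zeros(p)
        proposed = np.zeros(p)
        keep_idx = 0
        for it in range(config.n_iterations):
            # one Gibbs sweep of single-coordinate Metropolis updates
            steps = rng.standard_normal(p)
            unifs = rng.random(p)
            kicks = rng.random(p)
            for i in range(p):
                pr = prior_list[i]
                lo, hi = pr.bounds
                old = theta[i]
                if math.isfinite(lo) and math.isfinite(hi) and kicks[i] < 0.1:
                    # occasional uniform independence proposal over the
                    # support lets bounded parameters (changepoints) hop
                    # between modes; q is constant so the MH ratio is the
                    # plain posterior ratio
                    new = lo + (hi - lo) * rng.random()
                else:
                    new = _reflect(old + scales[i] * steps[i], lo, hi)
                theta[i] = new
                new_logprior = logprior - pr.logpdf(old) + pr.logpdf(new)
                new_logpost = log_density(theta) + new_logprior
                proposed[i] += 1
                if np.isfinite(new_logpost) and (
                        math.log(unifs[i] + 1e-300) < new_logpost - logpost):
                    logpost, logprior = new_logpost, new_logprior
                    accepted[i] += 1
                else:
                    theta[i] = old
            # adapt proposal scales toward ~0.44 acceptance during burn-in
            if it < config.n_burnin and (it + 1) % 50 == 0:
                rates = accepted / np.maximum(proposed, 1)
                scales *= np.exp(np.clip(rates - 0.44, -0.5, 0.5))
                accepted[:] = 0
                proposed[:] = 0
            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
                if keep_idx < n_keep:
                    for j, n in enumerate(names):
                        draws[n][chain, keep_idx] = theta[j]
                    keep_idx += 1

    return summarize_draws(draws, level)


# --- diagnostics -----------------------------------------------------------

def rhat(chains: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` is (m, n): m >= 2 chains of n >= 10 draws.  Classic
    between/within form: R-hat = sqrt(((n-1)/n W + B/n) / W).

    Raises
    ------
    ValueError
        On fewer than 2 chains, fewer than 10 draws, or zero
        within-chain variance.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 10:
        raise ValueError("need >= 2 chains with >= 10 draws each")
    m, n = arr.shape
    w = arr.var(axis=1, ddof=1).mean()
    if w == 0:
        raise ValueError("zero within-chain variance")
    b = n * arr.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def credible_interval(draws: Sequence[float],
                      level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval from posterior draws.

    Quantiles at (1-level)/2 and 1-(1-level)/2 with linear interpolation.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    arr = np.asarray(draws, dtype=float)
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(arr, [a, 1.0 - a])
    return float(lo), float(hi)


def intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """Whether two closed intervals overlap (touching counts as overlap).

    The significance rule is the negation: two groups differ when their
    95% CRIs do NOT overlap.
    """
    (alo, ahi), (blo, bhi) = a, b
    if alo > ahi or blo > bhi:
        raise ValueError("intervals must be ordered (lo <= hi)")
    return alo <= bhi and blo <= ahi


def pearson_residuals(y: Sequence[float], mu: Sequence[float],
                      family: str = "poisson", sd: float | None = None,
                      phi: float | None = None) -> np.ndarray:
    """Pearson residuals (y - mu) / sqrt(Var[y]) for the fitted family.

    Poisson: Var = mu (requires mu > 0).  Gaussian: Var = sd^2.  Beta with
    precision phi: Var = mu (1 - mu) / (1 + phi).  Plotted against fitted
    values as a convergence/fit diagnostic.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if family == "poisson":
        if (mu <= 0).any():
            raise ValueError("Poisson residuals need mu > 0")
        return (y - mu) / np.sqrt(mu)
    if family == "gaussian":
        if sd is None or sd <= 0:
            raise ValueError("gaussian residuals need sd > 0")
        return (y - mu) / sd
    if family == "beta":
        if phi is None or phi <= 0:
            raise ValueError("beta residuals need precision phi > 0")
        return (y - mu) / np.sqrt(mu * (1 - mu) / (1 + phi))
    raise ValueError(f"unknown family: {family!r}")
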