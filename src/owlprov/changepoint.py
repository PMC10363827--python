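"""Two-segment changepoint models: Poisson delivery rates and hierarchical
Gaussian nestling growth.

The delivery-rate model is a joined two-segment Poisson regression on the
log scale.  With domain origin ``delta0`` (fixed at 0: deliveries cannot
happen before sunset or before hatch), changepoint ``delta1`` and domain
maximum ``delta2`` (fixed at the largest observed x), the log expected
count per 15-min interval is

    log gamma(x) = beta1 * (min(x, delta1) - delta0)
                 + [x > delta1] * beta2 * (min(x, delta2) - delta1)

which is continuous at the changepoint and equals 0 at the origin, so the
expected count at x = 0 is exactly e^0 = 1.  The model is fitted with a
zero intercept and a log link (a Poisson mean must be positive).

Nestling growth uses the same joined-segment form per individual, on the
natural (gram) scale with a hatch-mass intercept, with per-nestling
intercepts, slopes and changepoints drawn from population-level normals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_data import DeliveryObservation, MassRecord
from .mcmc import (
    ChainConfig,
    HalfNormal,
    Normal,
    ParamSummary,
    PosteriorSummary,
    Uniform,
    credible_interval,
    sample_posterior,
    summarize_draws,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PiecewiseRateParams",
    "piecewise_log_rate",
    "DeliveryFitResult",
    "fit_delivery_changepoint",
    "fit_changepoint_counts",
    "rate_curve_summaries",
    "GrowthFitResult",
    "fit_growth_hierarchical",
    "changepoint_profile_oracle",
]

_LOGF_CLIP = 50.0  # log-rate clip guarding exp overflow in early iterations


@dataclass(frozen=True)
class PiecewiseRateParams:
    """Changepoint and segment slopes of the log-linear delivery intensity.

    ``delta0`` is the domain origin (0: sunset or hatch), ``delta2`` the
    domain maximum (largest observed x); only ``delta1`` is estimated.
    Slopes are per unit x (minute or day) on the log scale.
    """

    delta1: float
    beta1: float
    beta2: float
    delta0: float = 0.0
    delta2: float = math.inf

    def __post_init__(self) -> None:
        if not self.delta0 <= self.delta1 <= self.delta2:
            raise ValueError("need delta0 <= delta1 <= delta2")


def piecewise_log_rate(x, p: PiecewiseRateParams):
    """Log expected count per 15 min at x (scalar or array).

    Continuous in x and exactly 0 at ``x = delta0``.  Raises for x outside
    [delta0, delta2].
    """
    x = np.asarray(x, dtype=float)
    if (x < p.delta0).any() or (x > p.delta2).any():
        raise ValueError("x outside the model domain [delta0, delta2]")
    seg1 = p.beta1 * (np.minimum(x, p.delta1) - p.delta0)
    seg2 = np.where(x > p.delta1,
                    p.beta2 * (np.minimum(x, p.delta2) - p.delta1), 0.0)
    out = seg1 + seg2
    return float(out) if out.ndim == 0 else out


def _log_rate_raw(x: np.ndarray, d1, b1, b2) -> np.ndarray:
    # unchecked fast path used inside samplers; delta0=0, delta2=max(x)
    return b1 * np.minimum(x, d1) + b2 * np.maximum(x - d1, 0.0)


@dataclass
class DeliveryFitResult:
    """Posterior for one delivery changepoint fit plus the data fitted."""

    posterior: PosteriorSummary
    x: np.ndarray
    y: np.ndarray
    x_axis: str

    def params_mean(self) -> PiecewiseRateParams:
        """Posterior-mean parameters (delta2 fixed at max observed x)."""
        p = self.posterior
        return PiecewiseRateParams(
            delta1=p["delta1"].mean, beta1=p["beta1"].mean,
            beta2=p["beta2"].mean, delta2=float(self.x.max()),
        )

    def fitted_means(self) -> np.ndarray:
        """Expected counts at the observed x under posterior-mean params."""
        return np.exp(piecewise_log_rate(self.x, self.params_mean()))

    def pearson_residuals(self) -> np.ndarray:
        from .mcmc import pearson_residuals
        return pearson_residuals(self.y, self.fitted_means(), family="poisson")


def fit_changepoint_counts(x: Sequence[float], y: Sequence[int],
                           config: ChainConfig) -> DeliveryFitResult:
    """Bayesian two-segment Poisson changepoint fit on raw (x, count) pairs.

    Priors: delta1 ~ uniform(min x, max x); beta1, beta2 ~ normal(0, 1000).
    Zero intercept, log link.  Any R-hat >= 1.1 is carried as a warning on
    the returned posterior summary.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need >= 10 intervals")
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct x values")
    lo, hi = float(x.min()), float(x.max())

    def log_density(theta: np.ndarray) -> float:
        d1, b1, b2 = theta
        f = np.clip(_log_rate_raw(x, d1, b1, b2), -_LOGF_CLIP, _LOGF_CLIP)
        return float(y @ f - np.exp(f).sum())

    priors = {
        "delta1": Uniform(lo, hi),
        "beta1": Normal(0.0, 1000.0),
        "beta2": Normal(0.0, 1000.0),
    }
    posterior = sample_posterior(log_density, priors, config,
                                 starts=_moment_starts(x, y))
    return DeliveryFitResult(posterior=posterior, x=x, y=y, x_axis="x")


def _moment_starts(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Crude binned-mean starts: put the changepoint at the peak of the
    smoothed count profile and match the log-scale rise and fall.  Only
    used to initialize chains; the posterior does not depend on it."""
    edges = np.quantile(x, np.linspace(0, 1, 9))
    edges[-1] += 1e-9
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, 7)
    means = np.array([y[idx == i].mean() if (idx == i).any() else 0.0
                      for i in range(8)])
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(means))
    d1 = float(np.clip(centers[peak], x.min() + 1e-6, x.max() - 1e-6))
    log_peak = math.log(max(means[peak], 1e-3))
    log_end = math.log(max(means[-1], 1e-3))
    b1 = log_peak / max(d1, 1e-6)
    b2 = (log_end - log_peak) / max(x.max() - d1, 1e-6)
    return {"delta1": d1, "beta1": b1, "beta2": b2}


def fit_delivery_changepoint(obs: Sequence[DeliveryObservation], x_axis: str,
                             config: ChainConfig) -> DeliveryFitResult:
    """Fit the delivery changepoint model to filtered nest watches.

    ``x_axis`` selects the predictor: ``'minutes_after_sunset'`` for
    nightly models or ``'nest_age_days'`` for seasonal models.  The count
    is the total deliveries per interval (male + female + unknown).  The
    caller fits each weather category separately.
    """
    if x_axis not in ("minutes_after_sunset", "nest_age_days"):
        raise ValueError("x_axis must be 'minutes_after_sunset' or 'nest_age_days'")
    x = np.array([getattr(o, x_axis) for o in obs], dtype=float)
    y = np.array([o.n_total for o in obs], dtype=float)
    result = fit_changepoint_counts(x, y, config)
    result.x_axis = x_axis
    return result


def rate_curve_summaries(result: DeliveryFitResult,
                         x_grid: Sequence[float] | None = None,
                         level: float = 0.95) -> dict[str, ParamSummary]:
    """Posterior summaries of the fitted curve's mean, minimum and maximum.

    For every posterior draw the expected count e^f(x) is evaluated on
    ``x_grid`` (default: the sorted unique observed x values) and the
    curve's mean, min and max over the grid are taken; each functional's
    posterior is then summarized (mean + equal-tailed CRI).
    """
    if x_grid is None:
        x_grid = np.unique(result.x)
    grid = np.asarray(x_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty x grid")
    post = result.posterior
    d1 = post.flat("delta1")[:, None]
    b1 = post.flat("beta1")[:, None]
    b2 = post.flat("beta2")[:, None]
    f = b1 * np.minimum(grid[None, :], d1) + b2 * np.maximum(grid[None, :] - d1, 0)
    counts = np.exp(np.clip(f, -_LOGF_CLIP, _LOGF_CLIP))
    out = {}
    for name, vals in (("mean", counts.mean(axis=1)),
                       ("min", counts.min(axis=1)),
                       ("max", counts.max(axis=1))):
        lo, hi = credible_interval(vals, level)
        out[name] = ParamSummary(float(vals.mean()), lo, hi, float("nan"))
    return out


# --- hierarchical nestling growth ------------------------------------------

@dataclass
class GrowthFitResult:
    """Posterior for the hierarchical growth model.

    Population-level parameters: ``mu_alpha`` (hatch mass, g), ``mu_b1``
    (pre-changepoint growth, g/day), ``mu_b2`` (post-changepoint slope),
    ``mu_delta`` (population changepoint, days), their sds (``sd_*``) and
    the residual scale ``sigma_resid``.  Per-nestling draws are stored as
    ``alpha[<band>]`` etc.
    """

    posterior: PosteriorSummary
    bands: list[str]
    excluded: list[str] = field(default_factory=list)


def _group_nestlings(masses: Sequence[MassRecord]):
    groups: dict[str, list[tuple[float, float]]] = {}
    for m in masses:
        if m.cohort != "nestling":
            continue
        groups.setdefault(m.band_id, []).append(
            (float(m.nestling_age_days), float(m.mass_g)))
    return groups


def fit_growth_hierarchical(masses: Sequence[MassRecord],
                            config: ChainConfig) -> GrowthFitResult:
    """Fit the random-changepoint growth model to nestling weighings.

    mass_ij = alpha_j + b1_j min(age_ij, delta_j)
            + [age_ij > delta_j] b2_j (age_ij - delta_j) + eps,
    eps ~ N(0, sigma_resid^2), with per-nestling (alpha_j, b1_j, b2_j,
    delta_j) drawn from population normals.  A hatch-mass intercept is
    included because owlets have nonzero mass at hatching.  Priors:
    population changepoint uniform over the observed age range; intercept
    and slope hypermeans normal(0, 1000); hyper-sds half-normal(31.6);
    residual scale half-normal(100).

    Nestlings with fewer than two weighings are excluded with a warning.
    The sampler exploits the factorization of the likelihood over
    nestlings: per-nestling parameters are updated jointly across
    individuals with vectorized Metropolis steps, and hypermeans by
    conjugate Gibbs draws.
    """
    groups = _group_nestlings(masses)
    excluded = [b for b, v in groups.items() if len(v) < 2]
    for b in excluded:
        logger.warning("nestling %s has < 2 measurements; excluded", b)
    groups = {b: v for b, v in groups.items() if len(v) >= 2}
    if len(groups) < 5:
        raise ValueError("need >= 5 nestlings with >= 2 measurements")
    bands = sorted(groups)
    J = len(bands)
    T = max(len(groups[b]) for b in bands)
    ages = np.zeros((J, T))
    mass = np.zeros((J, T))
    mask = np.zeros((J, T), dtype=bool)
    for j, b in enumerate(bands):
        pts = sorted(groups[b])
        for t, (a, m) in enumerate(pts):
            ages[j, t], mass[j, t], mask[j, t] = a, m, True
    n_j = mask.sum(axis=1)
    n_tot = int(n_j.sum())
    age_lo, age_hi = float(ages[mask].min()), float(ages[mask].max())

    sd_hyper_scale = math.sqrt(1000.0)  # ~31.6, matches the slope priors
    sigma_scale = 100.0
    mu_prior_var = 1000.0

    def loglik_rows(alpha, b1, b2, delta, sigma):
        pred = (alpha[:, None] + b1[:, None] * np.minimum(ages, delta[:, None])
                + b2[:, None] * np.maximum(ages - delta[:, None], 0.0))
        r2 = np.where(mask, (mass - pred) ** 2, 0.0).sum(axis=1)
        return -0.5 * r2 / (sigma * sigma) - n_j * math.log(sigma)

    # crude per-nestling least-squares starts
    a0 = np.empty(J)
    s0 = np.empty(J)
    for j in range(J):
        aj, mj = ages[j, mask[j]], mass[j, mask[j]]
        slope, intercept = np.polyfit(aj, mj, 1) if np.ptp(aj) > 0 else (0.0, mj.mean())
        a0[j], s0[j] = intercept, slope

    n_keep = (config.n_iterations - config.n_burnin) // config.thin
    names = (["mu_alpha", "mu_b1", "mu_b2", "mu_delta",
              "sd_alpha", "sd_b1", "sd_b2", "sd_delta", "sigma_resid"]
             + [f"alpha[{b}]" for b in bands] + [f"b1[{b}]" for b in bands]
             + [f"b2[{b}]" for b in bands] + [f"delta[{b}]" for b in bands])
    draws = {n: np.empty((config.n_chains, n_keep)) for n in names}

    for chain in range(config.n_chains):
        rng = np.random.default_rng([int(config.seed) % (2**31), 7, chain])
        alpha = a0 + rng.normal(0, 1, J)
        b1 = np.maximum(s0, 0.1) + rng.normal(0, 0.1, J)
        b2 = rng.normal(0, 0.1, J)
        delta = np.clip(0.5 * (age_lo + age_hi) + rng.normal(0, 1, J),
                        age_lo, age_hi)
        mu = {"alpha": alpha.mean(), "b1": b1.mean(), "b2": b2.mean(),
              "delta": float(np.clip(delta.mean(), age_lo, age_hi))}
        sd = {"alpha": max(alpha.std(), 0.5), "b1": max(b1.std(), 0.2),
              "b2": 0.5, "delta": 2.0}
        pred_ll = loglik_rows(alpha, b1, b2, delta, 1.0)
        sigma = max(math.sqrt(-2 * pred_ll.sum() / n_tot), 0.5)

        vecs = {"alpha": alpha, "b1": b1, "b2": b2, "delta": delta}
        scales = {"alpha": 0.5, "b1": 0.1, "b2": 0.1, "delta": 1.0}
        sd_log_scale = {k: 0.3 for k in sd}
        sigma_log_scale = 0.2
        acc = {k: [0, 0] for k in
               list(scales) + [f"sd_{k}" for k in sd] + ["sigma"]}
        keep_idx = 0
        for it in range(config.n_iterations):
            cur_ll = loglik_rows(vecs["alpha"], vecs["b1"], vecs["b2"],
                                 vecs["delta"], sigma)
            # vectorized Metropolis over nestlings for each parameter type
            for k in ("alpha", "b1", "b2", "delta"):
                old = vecs[k]
                prop = old + scales[k] * rng.standard_normal(J)
                if k == "delta":
                    prop = age_lo + np.abs(prop - age_lo)
                    prop = age_hi - np.abs(age_hi - prop)
                    prop = np.clip(prop, age_lo, age_hi)
                vecs[k] = prop
                new_ll = loglik_rows(vecs["alpha"], vecs["b1"], vecs["b2"],
                                     vecs["delta"], sigma)
                dprior = (-0.5 * ((prop - mu[k]) ** 2 - (old - mu[k]) ** 2)
                          / (sd[k] ** 2))
                accept = np.log(rng.random(J) + 1e-300) < new_ll - cur_ll + dprior
                vecs[k] = np.where(accept, prop, old)
                cur_ll = np.where(accept, new_ll, cur_ll)
                acc[k][0] += int(accept.sum())
                acc[k][1] += J
            # conjugate Gibbs draws for the hypermeans
            for k in ("alpha", "b1", "b2"):
                prec = J / sd[k] ** 2 + 1.0 / mu_prior_var
                mean = (vecs[k].sum() / sd[k] ** 2) / prec
                mu[k] = rng.normal(mean, 1.0 / math.sqrt(prec))
            # population changepoint: truncated-normal Gibbs draw
            prec = J / sd["delta"] ** 2
            mean = vecs["delta"].mean()
            s = 1.0 / math.sqrt(prec)
            a_, b_ = (age_lo - mean) / s, (age_hi - mean) / s
            mu["delta"] = float(stats.truncnorm.ppf(rng.random(), a_, b_,
                                                    loc=mean, scale=s))
            # hyper-sds: log-scale Metropolis with half-normal priors
            for k in ("alpha", "b1", "b2", "delta"):
                old_sd = sd[k]
                new_sd = old_sd * math.exp(sd_log_scale[k] * rng.standard_normal())
                dev2 = float(((vecs[k] - mu[k]) ** 2).sum())
                def _sd_target(s_):
                    return (-J * math.log(s_) - 0.5 * dev2 / (s_ * s_)
                            - 0.5 * s_ * s_ / sd_hyper_scale ** 2
                            + math.log(s_))  # + Jacobian of the log transform
                if math.log(rng.random() + 1e-300) < _sd_target(new_sd) - _sd_target(old_sd):
                    sd[k] = new_sd
                    acc[f"sd_{k}"][0] += 1
                acc[f"sd_{k}"][1] += 1
            # residual scale
            old_sig = sigma
            new_sig = old_sig * math.exp(sigma_log_scale * rng.standard_normal())
            r2 = -2 * (cur_ll + n_j * math.log(old_sig)).sum() * old_sig ** 2
            def _sig_target(s_):
                return (-n_tot * math.log(s_) - 0.5 * r2 / (s_ * s_)
                        - 0.5 * s_ * s_ / sigma_scale ** 2 + math.log(s_))
            if math.log(rng.random() + 1e-300) < _sig_target(new_sig) - _sig_target(old_sig):
                sigma = new_sig
                acc["sigma"][0] += 1
            acc["sigma"][1] += 1
            # scale adaptation during burn-in
            if it < config.n_burnin and (it + 1) % 50 == 0:
                for k in ("alpha", "b1", "b2", "delta"):
                    rate = acc[k][0] / max(acc[k][1], 1)
                    scales[k] *= math.exp(np.clip(rate - 0.44, -0.5, 0.5))
                    acc[k] = [0, 0]
                    rate = acc[f"sd_{k}"][0] / max(acc[f"sd_{k}"][1], 1)
                    sd_log_scale[k] *= math.exp(np.clip(rate - 0.44, -0.5, 0.5))
                    acc[f"sd_{k}"] = [0, 0]
                rate = acc["sigma"][0] / max(acc["sigma"][1], 1)
                sigma_log_scale *= math.exp(np.clip(rate - 0.44, -0.5, 0.5))
                acc["sigma"] = [0, 0]
            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
                if keep_idx < n_keep:
                    row = ([mu["alpha"], mu["b1"], mu["b2"], mu["delta"],
                            sd["alpha"], sd["b1"], sd["b2"], sd["delta"], sigma]
                           + list(vecs["alpha"]) + list(vecs["b1"])
                           + list(vecs["b2"]) + list(vecs["delta"]))
                    for nm, v in zip(names, row):
                        draws[nm][chain, keep_idx] = v
                    keep_idx += 1

    posterior = summarize_draws(draws)
    return GrowthFitResult(posterior=posterior, bands=bands, excluded=excluded)


# --- profile-likelihood oracle ---------------------------------------------

def changepoint_profile_oracle(
    x: Sequence[float], y: Sequence[int], grid: Sequence[float],
    return_profile: bool = False,
):
    """Maximum-likelihood changepoint by profile likelihood on a grid.

    For each fixed delta1 on ``grid`` the two-slope zero-intercept Poisson
    model is fitted by ML (log link); the returned changepoint maximizes
    the profile likelihood.  Ties within 1e-8 log-likelihood break to the
    smallest grid value.  Serves as an independent frequentist cross-check
    of the Bayesian posterior mode on large datasets.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 1:
        raise ValueError("empty grid")
    if grid.min() < x.min() - 1e-9 or grid.max() > x.max() + 1e-9:
        raise ValueError("grid must lie within the data range")
    llf = np.full(grid.size, -np.inf)
    coefs = np.zeros((grid.size, 2))
    for i, d1 in enumerate(grid):
        x1 = np.minimum(x, d1)
        x2 = np.maximum(x - d1, 0.0)
        X = np.column_stack([x1, x2])
        active = np.ptp(X, axis=0) > 1e-12
        if not active.any():
            continue
        try:
            res = sm.GLM(y, X[:, active], family=sm.families.Poisson()).fit()
        except Exception:
            continue
        llf[i] = res.llf
        coefs[i, active] = res.params
        coefs[i, ~active] = np.nan
    best = int(np.flatnonzero(llf >= llf.max() - 1e-8)[0])
    if return_profile:
        return (float(grid[best]), float(coefs[best, 0]), float(coefs[best, 1]),
                pd.DataFrame({"delta1": grid, "llf": llf}))
    return float(grid[best]), float(coefs[best, 0]), float(coefs[best, 1])
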