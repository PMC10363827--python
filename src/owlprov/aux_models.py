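"""Supporting inference stages: division-of-labor beta GLM, adult-mass
mixed model, and productivity Poisson GLM.

Division of labor is the share of sexed deliveries made by the female in
one watch interval; unknown-sex deliveries are excluded.  Adult mass is
regressed on Julian day with per-individual random intercepts and slopes
(mass declines over the nestling period are expected in females, which do
all brooding).  Productivity compares clutch size, brood size and
fledgling counts between weather categories through a Poisson GLM with a
0/1 category indicator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, gammaln

from .io_data import DeliveryObservation, MassRecord
from .mcmc import (
    ChainConfig,
    Flat,
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
    "LaborObservation",
    "ProductivityOutcome",
    "female_proportion",
    "squeeze_proportion",
    "build_labor_dataset",
    "fit_labor_beta",
    "fit_mass_trend",
    "MassFitResult",
    "fit_productivity",
    "ProductivityFit",
]

# The analysis-standard wide slope/intercept prior is normal with variance 1000.
# A uniform with the same mean and variance (half-width sqrt(3000) ~ 54.77)
# is available for sensitivity checks, since the source description of
# these priors is ambiguous between the two.
_UNIFORM_HALFWIDTH = math.sqrt(3000.0)


def _wide_prior(kind: str):
    if kind == "normal":
        return Normal(0.0, 1000.0)
    if kind == "uniform":
        return Uniform(-_UNIFORM_HALFWIDTH, _UNIFORM_HALFWIDTH)
    raise ValueError("prior kind must be 'normal' or 'uniform'")


@dataclass(frozen=True)
class LaborObservation:
    """Female share of sexed deliveries in one watch interval."""

    nest_id: str
    x: float  # minutes after sunset or nest age (days)
    p_female: float
    n_sexed: int

    def __post_init__(self) -> None:
        if self.n_sexed < 1:
            raise ValueError("n_sexed must be >= 1")
        if not 0.0 <= self.p_female <= 1.0:
            raise ValueError("p_female must lie in [0, 1]")


@dataclass(frozen=True)
class ProductivityOutcome:
    """One nest's count for one outcome with its weather-category flag."""

    nest_id: str
    outcome: str  # clutch | brood | fledglings
    value: int
    category_indicator: int  # 1 = wet (or warm), 0 = dry (or cold)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("value must be >= 0")
        if self.category_indicator not in (0, 1):
            raise ValueError("category_indicator must be 0 or 1")


def female_proportion(obs: DeliveryObservation,
                      x_axis: str = "nest_age_days") -> LaborObservation | None:
    """Raw female share of the sexed deliveries in one interval.

    Unknown-sex deliveries are excluded; returns None when the interval
    had no sexed deliveries at all.
    """
    n = obs.n_female + obs.n_male
    if n < 1:
        return None
    return LaborObservation(
        nest_id=obs.nest_id,
        x=float(getattr(obs, x_axis)),
        p_female=obs.n_female / n,
        n_sexed=n,
    )


def squeeze_proportion(p: float, n_total: int) -> float:
    """Smithson-Verkuilen squeeze p' = (p (N-1) + 0.5) / N.

    Maps proportions off the {0, 1} boundary so a beta likelihood (whose
    support is the open interval) applies; N is the total number of sexed
    deliveries in the dataset.  Strictly monotone in p and bounded inside
    (0, 1) for N >= 1.
    """
    if n_total < 1:
        raise ValueError("need N >= 1")
    return (p * (n_total - 1) + 0.5) / n_total


def build_labor_dataset(obs: Sequence[DeliveryObservation],
                        x_axis: str = "nest_age_days") -> list[LaborObservation]:
    """Per-interval labor observations with the boundary squeeze applied.

    The squeeze uses N = the total sexed deliveries across the dataset,
    so boundary handling is dataset-level, not per interval.
    """
    raw = [lo for o in obs if (lo := female_proportion(o, x_axis)) is not None]
    n_total = sum(lo.n_sexed for lo in raw)
    return [
        LaborObservation(lo.nest_id, lo.x,
                         squeeze_proportion(lo.p_female, n_total), lo.n_sexed)
        for lo in raw
    ]


def fit_labor_beta(data: Sequence[LaborObservation], config: ChainConfig,
                   prior_kind: str = "normal",
                   weight_by_n: bool = False) -> PosteriorSummary:
    """Bayesian beta GLM of the female delivery share.

    logit(mu_i) = b0 + b1 x_i with beta precision phi:
    p_i ~ Beta(mu_i phi, (1 - mu_i) phi).  Priors: b0, b1 normal(0, 1000)
    (or the matched uniform); phi half-normal(100).  One data point per
    interval regardless of how many deliveries were sexed; pass
    ``weight_by_n=True`` to weight each interval's log-likelihood by its
    number of sexed deliveries.  Run per weather category by the caller;
    between-category differences are judged by CRI overlap on b0 and b1.
    """
    if len(data) < 10:
        raise ValueError("need >= 10 labor observations")
    x = np.array([d.x for d in data])
    p = np.array([d.p_female for d in data])
    w = (np.array([d.n_sexed for d in data], dtype=float)
         if weight_by_n else np.ones(len(data)))
    if (p <= 0).any() or (p >= 1).any():
        raise ValueError("proportions must be squeezed off {0,1} first")
    logp = np.log(p)
    log1mp = np.log1p(-p)

    def log_density(theta: np.ndarray) -> float:
        b0, b1, phi = theta
        if phi <= 0:
            return -math.inf
        mu = expit(b0 + b1 * x)
        a = np.clip(mu * phi, 1e-8, None)
        b = np.clip((1 - mu) * phi, 1e-8, None)
        ll = (gammaln(a + b) - gammaln(a) - gammaln(b)
              + (a - 1) * logp + (b - 1) * log1mp)
        return float((w * ll).sum())

    priors = {
        "b0": _wide_prior(prior_kind),
        "b1": _wide_prior(prior_kind),
        "phi": HalfNormal(100.0),
    }
    return sample_posterior(log_density, priors, config)


@dataclass
class MassFitResult:
    """Posterior for one adult-mass mixed-model fit."""

    posterior: PosteriorSummary
    bands: list[str]

    @property
    def slope_significant(self) -> bool:
        lo, hi = self.posterior.cri("b")
        return not (lo <= 0.0 <= hi)


def fit_mass_trend(masses: Sequence[MassRecord], cohort: str,
                   config: ChainConfig, prior_kind: str = "normal",
                   center_julian: bool = False) -> MassFitResult:
    """Mixed model of adult mass on Julian day.

    mass_ij = (a + u_j) + (b + v_j) julian_ij + eps with random intercepts
    u_j and slopes v_j per band (individual), normal population
    distributions with half-normal(31.6) sd priors, residual sd
    half-normal(100), and wide fixed-effect priors.  Individuals measured
    once still inform the intercepts; their slopes are prior-dominated.
    A significant mass trend means the fixed slope CRI excludes zero.

    Julian day enters raw by default to mirror the original analysis;
    ``center_julian=True`` centres it for numerical stability.
    """
    recs = [m for m in masses if m.cohort == cohort]
    bands = sorted({m.band_id for m in recs})
    if len(bands) < 5:
        raise ValueError("need >= 5 individuals")
    band_idx = {b: i for i, b in enumerate(bands)}
    idx = np.array([band_idx[m.band_id] for m in recs])
    day = np.array([float(m.julian_day) for m in recs])
    y = np.array([m.mass_g for m in recs])
    J = len(bands)
    n = len(recs)

    # Sampling always happens on the mean-centred day scale: the raw
    # scale makes intercept and slope almost perfectly correlated (days
    # are ~150-200), which defeats coordinate-wise proposals.  With
    # center_julian=False the intercept draws are transformed back to
    # the raw scale afterwards; the wide prior is applied to the
    # raw-scale intercept either way, so the reported posterior is the
    # raw-scale model's.
    day_mean = 0.0 if center_julian else float(day.mean())
    dayc = day - day.mean()
    a_prior = _wide_prior(prior_kind)

    def log_density(theta: np.ndarray) -> float:
        a_c, b, sd_u, sd_v, sigma = theta[:5]
        if min(sd_u, sd_v, sigma) <= 0:
            return -math.inf
        u = theta[5:5 + J]
        v = theta[5 + J:5 + 2 * J]
        pred = a_c + u[idx] + (b + v[idx]) * dayc
        ll = -0.5 * ((y - pred) ** 2).sum() / (sigma * sigma) - n * math.log(sigma)
        ll += -0.5 * (u * u).sum() / (sd_u * sd_u) - J * math.log(sd_u)
        ll += -0.5 * (v * v).sum() / (sd_v * sd_v) - J * math.log(sd_v)
        # wide prior on the raw-scale intercept a = a_c - b * day_mean
        ll += a_prior.logpdf(a_c - b * day_mean)
        return float(ll)

    priors: dict = {
        "a_c": Flat(0.0, 1.0),
        "b": _wide_prior(prior_kind),
        "sd_u": HalfNormal(math.sqrt(1000.0)),
        "sd_v": HalfNormal(math.sqrt(1000.0)),
        "sigma": HalfNormal(100.0),
    }
    for bnd in bands:
        priors[f"u[{bnd}]"] = Flat(0.0, 1.0)
    for bnd in bands:
        priors[f"v[{bnd}]"] = Flat(0.0, 0.05)
    slope = (float(np.polyfit(dayc, y, 1)[0]) if np.ptp(dayc) > 0 else 0.0)
    resid_sd = float(np.std(y - slope * dayc - y.mean())) or 1.0
    starts = {"a_c": float(y.mean()), "b": slope,
              "sd_u": resid_sd, "sd_v": 0.01, "sigma": resid_sd}
    posterior = sample_posterior(log_density, priors, config, starts=starts)
    # report the intercept on the requested scale
    a_draws = (posterior.draws["a_c"]
               - posterior.draws["b"] * (day.mean() if not center_julian else 0.0))
    draws = {"a": a_draws, **{k: v for k, v in posterior.draws.items()
                              if k != "a_c"}}
    posterior = summarize_draws(draws)
    return MassFitResult(posterior=posterior, bands=bands)


@dataclass
class ProductivityFit:
    """Posterior for one productivity contrast.

    ``c1`` is the log-scale category effect (significant when its CRI
    excludes zero); ``category_means`` holds posterior summaries of the
    two category means exp(c0) and exp(c0 + c1) for overlap displays.
    """

    posterior: PosteriorSummary
    category_means: dict[str, ParamSummary]
    warnings: list[str]

    @property
    def effect_significant(self) -> bool:
        lo, hi = self.posterior.cri("c1")
        return not (lo <= 0.0 <= hi)


def fit_productivity(data: Sequence[ProductivityOutcome], config: ChainConfig,
                     prior_kind: str = "normal") -> ProductivityFit:
    """Poisson GLM comparing a productivity outcome between categories.

    value_i ~ Poisson(exp(c0 + c1 indicator_i)) with wide priors on c0
    and c1.  Besides the effect posterior, returns posterior summaries of
    the per-category mean counts.  A category whose counts are all zero
    leaves c1 prior-dominated; this is flagged, not fatal.
    """
    if len(data) < 2:
        raise ValueError("need productivity records for both categories")
    y = np.array([d.value for d in data], dtype=float)
    ind = np.array([d.category_indicator for d in data], dtype=float)
    warnings = []
    for g in (0, 1):
        sel = ind == g
        if not sel.any():
            raise ValueError(f"no records with category_indicator={g}")
        if y[sel].sum() == 0:
            warnings.append(
                f"all counts zero for category {g}: effect is prior-dominated")

    def log_density(theta: np.ndarray) -> float:
        c0, c1 = theta
        eta = np.clip(c0 + c1 * ind, -50, 50)
        return float(y @ eta - np.exp(eta).sum())

    priors = {"c0": _wide_prior(prior_kind), "c1": _wide_prior(prior_kind)}
    posterior = sample_posterior(log_density, priors, config)
    posterior.warnings.extend(warnings)
    c0 = posterior.flat("c0")
    c1 = posterior.flat("c1")
    means = {}
    for name, vals in (("mean_cat0", np.exp(c0)), ("mean_cat1", np.exp(c0 + c1))):
        lo, hi = credible_interval(vals)
        means[name] = ParamSummary(float(vals.mean()), lo, hi, float("nan"))
    return ProductivityFit(posterior=posterior, category_means=means,
                           warnings=warnings)
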