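"""End-to-end orchestration: classify years, filter observations, fit
every model family per weather category, and write a self-describing
report bundle.

The bundle mirrors the study's result surfaces: a yearly climate/
productivity summary, posterior delivery-rate summaries (mean/min/max per
15 min), changepoint/slope posteriors, and productivity effect
posteriors.  Every number in the bundle is traceable to (model, category,
parameter, seed), and two runs with the same seed produce byte-identical
summary JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .aux_models import (
    ProductivityOutcome,
    build_labor_dataset,
    fit_labor_beta,
    fit_mass_trend,
    fit_productivity,
)
from .changepoint import fit_delivery_changepoint, fit_growth_hierarchical, rate_curve_summaries
from .io_data import (
    exclude_unknown_fate,
    filter_observations,
    read_table,
    read_weather_hourly,
)
from .mcmc import ChainConfig
from .weather import (
    Baseline,
    aggregate_owl_year,
    classify_year,
    correlation_screen,
    derive_baseline_ratios,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""


@dataclass
class PipelineConfig:
    """Inputs, chain settings and output location for a full run.

    Default chain settings restate the published analysis: deliveries and
    productivity 3 x 20,000 (burn-in 4,000), growth 3 x 4,000 (2,000),
    labor 3 x 10,000 (1,000), adult mass 3 x 200,000 (50,000), thinning 1
    throughout.  They are deliberately overridable: scaled-down runs are
    appropriate for smoke tests.
    """

    deliveries_path: str
    nests_path: str
    masses_path: str
    weather_path: str
    out_dir: str
    seed: int = 0
    baseline: Baseline | None = None  # None: derive ratios from the data
    chains_deliveries: ChainConfig = field(
        default_factory=lambda: ChainConfig(20000, 4000))
    chains_growth: ChainConfig = field(
        default_factory=lambda: ChainConfig(4000, 2000))
    chains_labor: ChainConfig = field(
        default_factory=lambda: ChainConfig(10000, 1000))
    chains_mass: ChainConfig = field(
        default_factory=lambda: ChainConfig(200000, 50000))
    chains_productivity: ChainConfig = field(
        default_factory=lambda: ChainConfig(20000, 4000))

    def _seeded(self, cfg: ChainConfig, salt: int) -> ChainConfig:
        return ChainConfig(cfg.n_iterations, cfg.n_burnin, cfg.n_chains,
                           cfg.thin, seed=(self.seed * 1000 + salt) % (2**31))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _summary_json(summary) -> dict:
    return summary.to_dict()


def _param_summaries_json(d: dict) -> dict:
    return {k: {"mean": v.mean, "cri_lo": v.cri_lo, "cri_hi": v.cri_hi}
            for k, v in d.items()}


@_stage("weather")
def _classify_years(config: PipelineConfig, season_years: list[int]):
    path = Path(config.weather_path)
    if not path.exists():
        raise FileNotFoundError(f"weather path not found: {path}")
    hourly = read_weather_hourly(path)
    years = [aggregate_owl_year(hourly, y) for y in sorted(set(season_years))]
    baseline = config.baseline or derive_baseline_ratios(years)
    classified = {y.year_label: classify_year(y, baseline) for y in years}
    r, p = correlation_screen([y.total_precip_mm for y in years],
                              [y.mean_daily_min_temp_c for y in years])
    return classified, baseline, (r, p)


def _year_of(obs) -> int:
    # watches happen May-July, so the breeding year is the calendar year
    return obs.obs_date.year


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Stages: weather classification -> observation filters -> delivery
    changepoint models (nightly & seasonal, per category) -> labor,
    growth, mass and productivity models -> summary tables + manifest.
    Any stage failure raises :class:`PipelineError` naming the stage;
    convergence warnings are collected in the bundle, not raised.

    Returns the bundle as a dict; JSON artifacts are written under
    ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    # --- ingest ---
    for label, p in (("deliveries", config.deliveries_path),
                     ("nests", config.nests_path),
                     ("masses", config.masses_path)):
        if not Path(p).exists():
            raise PipelineError(f"stage 'ingest' failed: {label} path not "
                                f"found: {p}")
    deliveries = read_table(config.deliveries_path, "deliveries")
    nests = read_table(config.nests_path, "nests")
    masses = read_table(config.masses_path, "masses")
    warnings += [f"deliveries: {m}" for m in deliveries.errors]
    warnings += [f"nests: {m}" for m in nests.errors]
    warnings += [f"masses: {m}" for m in masses.errors]

    # --- weather classification ---
    season_years = sorted({n.year for n in nests.records}
                          | {_year_of(o) for o in deliveries.records})
    classified, baseline, (corr_r, corr_p) = _classify_years(config, season_years)

    # --- filters ---
    filt = filter_observations(deliveries.records)
    kept_nests, kept_obs = exclude_unknown_fate(nests.records, filt.retained)

    def category_of(year: int, contrast: str) -> str | None:
        yc = classified.get(year)
        if yc is None:
            return None
        return yc.wet_dry if contrast == "wet_dry" else yc.warm_cold

    obs_by_cat: dict[str, list] = {c: [] for c in ("wet", "dry", "warm", "cold")}
    for o in kept_obs:
        for contrast in ("wet_dry", "warm_cold"):
            cat = category_of(_year_of(o), contrast)
            if cat:
                obs_by_cat[cat].append(o)

    bundle: dict = {
        "baseline": {
            "historical_mean_precip_mm": baseline.historical_mean_precip_mm,
            "historical_mean_min_temp_c": baseline.historical_mean_min_temp_c,
            "precip_ratio": baseline.precip_ratio,
            "temp_ratio": baseline.temp_ratio,
        },
        "correlation": {"r": corr_r, "p": corr_p},
        "year_climate": [
            {"year": y.year_label, "precip_mm": y.total_precip_mm,
             "min_temp_c": y.mean_daily_min_temp_c, "wet_dry": y.wet_dry,
             "warm_cold": y.warm_cold}
            for y in classified.values()
        ],
        "drop_counts": filt.dropped,
        "deliveries": {},
        "rate_summaries": {},
        "labor": {},
        "growth": {},
        "mass": {},
        "productivity": {},
    }

    # --- delivery changepoint models ---
    try:
        salt = 10
        for cat, cat_obs in obs_by_cat.items():
            for axis, xcol in (("night", "minutes_after_sunset"),
                               ("season", "nest_age_days")):
                if len(cat_obs) < 10:
                    warnings.append(f"deliveries {cat}/{axis}: too few intervals")
                    continue
                cfg = config._seeded(config.chains_deliveries, salt)
                salt += 1
                fit = fit_delivery_changepoint(cat_obs, xcol, cfg)
                key = f"{cat}/{axis}"
                bundle["deliveries"][key] = _summary_json(fit.posterior)
                bundle["rate_summaries"][key] = _param_summaries_json(
                    rate_curve_summaries(fit))
                warnings += [f"deliveries {key}: {w}"
                             for w in fit.posterior.warnings]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'deliveries' failed: {exc}") from exc

    # --- division of labor ---
    try:
        salt = 30
        for cat, cat_obs in obs_by_cat.items():
            for axis, xcol in (("night", "minutes_after_sunset"),
                               ("season", "nest_age_days")):
                labor = build_labor_dataset(cat_obs, xcol)
                if len(labor) < 10:
                    warnings.append(f"labor {cat}/{axis}: too few observations")
                    continue
                cfg = config._seeded(config.chains_labor, salt)
                salt += 1
                summary = fit_labor_beta(labor, cfg)
                bundle["labor"][f"{cat}/{axis}"] = _summary_json(summary)
                warnings += [f"labor {cat}/{axis}: {w}" for w in summary.warnings]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'labor' failed: {exc}") from exc

    # --- nestling growth (per category) ---
    try:
        salt = 50
        nestlings = [m for m in masses.records if m.cohort == "nestling"]
        year_of_band: dict[str, int] = {}
        for m in nestlings:
            year_of_band.setdefault(m.band_id, m.obs_date.year)
        for cat in ("wet", "dry", "warm", "cold"):
            contrast = "wet_dry" if cat in ("wet", "dry") else "warm_cold"
            cat_masses = [m for m in nestlings
                          if category_of(year_of_band[m.band_id], contrast) == cat]
            if len({m.band_id for m in cat_masses}) < 5:
                warnings.append(f"growth {cat}: too few nestlings")
                continue
            cfg = config._seeded(config.chains_growth, salt)
            salt += 1
            fit = fit_growth_hierarchical(cat_masses, cfg)
            pops = {k: v for k, v in fit.posterior.params.items()
                    if "[" not in k}
            bundle["growth"][cat] = {
                "params": {k: {"mean": v.mean, "cri_lo": v.cri_lo,
                               "cri_hi": v.cri_hi, "rhat": v.rhat}
                           for k, v in pops.items()},
                "n_nestlings": len(fit.bands),
                "excluded": fit.excluded,
            }
            warnings += [f"growth {cat}: {w}" for w in fit.posterior.warnings
                         if "[" not in w]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'growth' failed: {exc}") from exc

    # --- adult mass ---
    try:
        salt = 70
        adults = [m for m in masses.records if m.cohort != "nestling"]
        for cat in ("wet", "dry", "warm", "cold"):
            contrast = "wet_dry" if cat in ("wet", "dry") else "warm_cold"
            for cohort in ("adult_female", "adult_male"):
                cat_masses = [m for m in adults if m.cohort == cohort and
                              category_of(m.obs_date.year, contrast) == cat]
                if len({m.band_id for m in cat_masses}) < 5:
                    warnings.append(f"mass {cat}/{cohort}: too few individuals")
                    continue
                cfg = config._seeded(config.chains_mass, salt)
                salt += 1
                fit = fit_mass_trend(cat_masses, cohort, cfg)
                pops = {k: v for k, v in fit.posterior.params.items()
                        if "[" not in k}
                bundle["mass"][f"{cat}/{cohort}"] = {
                    "params": {k: {"mean": v.mean, "cri_lo": v.cri_lo,
                                   "cri_hi": v.cri_hi, "rhat": v.rhat}
                               for k, v in pops.items()},
                    "slope_significant": fit.slope_significant,
                }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'mass' failed: {exc}") from exc

    # --- productivity ---
    try:
        salt = 90
        for contrast, one_label in (("wet_dry", "wet"), ("warm_cold", "warm")):
            for outcome in ("clutch", "brood", "fledglings"):
                data = []
                for n in kept_nests:
                    val = getattr(n, outcome)
                    cat = category_of(n.year, contrast)
                    if val is None or cat is None:
                        continue
                    data.append(ProductivityOutcome(
                        n.nest_id, outcome, val,
                        1 if cat == one_label else 0))
                if len(data) < 10:
                    warnings.append(f"productivity {contrast}/{outcome}: "
                                    "too few nests")
                    continue
                cfg = config._seeded(config.chains_productivity, salt)
                salt += 1
                fit = fit_productivity(data, cfg)
                bundle["productivity"][f"{contrast}/{outcome}"] = {
                    "posterior": _summary_json(fit.posterior),
                    "category_means": _param_summaries_json(fit.category_means),
                    "effect_significant": fit.effect_significant,
                }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'productivity' failed: {exc}") from exc

    bundle["warnings"] = warnings

    # --- write artifacts ---
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(bundle, indent=2, sort_keys=True))
    config_repr = json.dumps(
        {k: (asdict(v) if isinstance(v, ChainConfig) else
             (asdict(v) if isinstance(v, Baseline) else v))
         for k, v in asdict(config).items()}, sort_keys=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_repr.encode()).hexdigest(),
        "n_delivery_intervals": len(filt.retained),
        "n_nests": len(kept_nests),
        "n_mass_records": len(masses.records),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    pd.DataFrame(bundle["year_climate"]).to_csv(
        out_dir / "year_climate.csv", index=False)
    return bundle
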