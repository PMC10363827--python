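"""Owl-year weather aggregation, wet/dry & warm/cold classification, and
covariate-window selection.

An *owl year* for breeding season Y runs 1 June of calendar year Y-1
through 31 May of Y: the twelve months of weather preceding (and leading
into) the breeding season.  Years are classified against the 1950--2000
historical baseline: a year is *wet* when its total precipitation exceeds
a fixed fraction of the historical mean (the fraction is the study-period
mean expressed as a share of the historical mean), and *warm*/*cold*
analogously for mean daily minimum temperature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "YearClimate",
    "Baseline",
    "CovariateWindow",
    "aggregate_owl_year",
    "classify_year",
    "derive_baseline_ratios",
    "correlation_screen",
    "select_window_aic",
    "window_covariate",
    "STANDARD_TEMP_WINDOWS",
    "STANDARD_PRECIP_WINDOWS",
]

# Historical (1950-2000) means for the study area, as printed in the
# source climate summary.
HISTORICAL_MEAN_PRECIP_MM = 418.1
HISTORICAL_MEAN_MIN_TEMP_C = -6.4


@dataclass(frozen=True)
class YearClimate:
    """Aggregate weather for one owl year.

    ``year_label`` is the breeding-season calendar year; the aggregation
    window ends 31 May of that year.  ``wet_dry`` / ``warm_cold`` are None
    until :func:`classify_year` assigns them.
    """

    year_label: int
    total_precip_mm: float
    mean_daily_min_temp_c: float
    wet_dry: str | None = None
    warm_cold: str | None = None

    def __post_init__(self) -> None:
        if self.total_precip_mm < 0:
            raise ValueError("total_precip_mm must be >= 0")


@dataclass(frozen=True)
class Baseline:
    """Historical means and the classification ratios derived from them."""

    historical_mean_precip_mm: float = HISTORICAL_MEAN_PRECIP_MM
    historical_mean_min_temp_c: float = HISTORICAL_MEAN_MIN_TEMP_C
    precip_ratio: float = 0.718
    temp_ratio: float = 0.465

    def __post_init__(self) -> None:
        for r in (self.precip_ratio, self.temp_ratio):
            if not (0 < r < 2):
                raise ValueError("classification ratios must lie in (0, 2)")
        if not np.isfinite([self.historical_mean_precip_mm,
                            self.historical_mean_min_temp_c]).all():
            raise ValueError("historical means must be finite")


@dataclass(frozen=True)
class CovariateWindow:
    """A candidate yearly weather covariate: a variable over a month span.

    ``start``/``end`` are (month, year_offset) pairs where offset 0 is the
    breeding calendar year and -1 the preceding year; e.g. the full owl
    year is (6, -1)..(5, 0) and the nestling period is (6, 0)..(7, 0).
    """

    variable: str  # precip_total | temp_mean | temp_min | temp_max
    start: tuple[int, int]
    end: tuple[int, int]
    label: str = ""

    _VARS = ("precip_total", "temp_mean", "temp_min", "temp_max")

    def __post_init__(self) -> None:
        if self.variable not in self._VARS:
            raise ValueError(f"variable must be one of {self._VARS}")

    @property
    def name(self) -> str:
        return self.label or f"{self.variable}_{self.start}_{self.end}"


# The candidate windows screened before the main analysis: three daily
# temperature statistics over the nestling period (Jun-Jul) and the full
# owl year (Jun-May), and four precipitation spans.
STANDARD_TEMP_WINDOWS = [
    CovariateWindow("temp_mean", (6, 0), (7, 0), "temp_mean_jun_jul"),
    CovariateWindow("temp_min", (6, 0), (7, 0), "temp_min_jun_jul"),
    CovariateWindow("temp_max", (6, 0), (7, 0), "temp_max_jun_jul"),
    CovariateWindow("temp_mean", (6, -1), (5, 0), "temp_mean_jun_may"),
    CovariateWindow("temp_min", (6, -1), (5, 0), "temp_min_jun_may"),
    CovariateWindow("temp_max", (6, -1), (5, 0), "temp_max_jun_may"),
]
STANDARD_PRECIP_WINDOWS = [
    CovariateWindow("precip_total", (6, 0), (7, 0), "precip_jun_jul"),
    CovariateWindow("precip_total", (6, -1), (5, 0), "precip_jun_may"),
    CovariateWindow("precip_total", (1, 0), (6, 0), "precip_jan_jun"),
    CovariateWindow("precip_total", (7, -1), (12, -1), "precip_jul_dec"),
]


def _window_bounds(season_year: int, start: tuple[int, int],
                   end: tuple[int, int]) -> tuple[pd.Timestamp, pd.Timestamp]:
    s_month, s_off = start
    e_month, e_off = end
    lo = pd.Timestamp(year=season_year + s_off, month=s_month, day=1)
    hi = (pd.Timestamp(year=season_year + e_off, month=e_month, day=1)
          + pd.offsets.MonthEnd(0) + pd.Timedelta(hours=23, minutes=59, seconds=59))
    return lo, hi


def _slice_window(hourly: pd.DataFrame, lo: pd.Timestamp,
                  hi: pd.Timestamp) -> pd.DataFrame:
    m = (hourly["timestamp"] >= lo) & (hourly["timestamp"] <= hi)
    return hourly.loc[m]


def aggregate_owl_year(hourly: pd.DataFrame, season_year: int) -> YearClimate:
    """Aggregate an hourly series over one owl year (unlabelled).

    Total precipitation is the sum of hourly precipitation over
    [1 Jun season_year-1, 31 May season_year]; temperature is the mean
    over days of each day's minimum hourly reading.  Days with no
    temperature reading are skipped in the mean; precipitation gaps
    contribute zero (logged), since archive data have outages.

    Raises
    ------
    ValueError
        If the window contains no data at all.
    """
    lo, hi = _window_bounds(season_year, (6, -1), (5, 0))
    win = _slice_window(hourly, lo, hi)
    if win.empty:
        raise ValueError(f"no hourly data in owl year {season_year} "
                         f"({lo.date()}..{hi.date()})")
    n_days_expected = (hi.normalize() - lo).days + 1
    n_days_seen = win["timestamp"].dt.normalize().nunique()
    if n_days_seen < n_days_expected:
        logger.warning(
            "owl year %d: %d of %d days missing; precipitation gaps count 0",
            season_year, n_days_expected - n_days_seen, n_days_expected,
        )
    total_precip = float(win["precip_mm"].fillna(0).sum())
    temps = win.dropna(subset=["temp_c"])
    daily_min = temps.groupby(temps["timestamp"].dt.normalize())["temp_c"].min()
    if daily_min.empty:
        raise ValueError(f"no temperature readings in owl year {season_year}")
    return YearClimate(
        year_label=season_year,
        total_precip_mm=total_precip,
        mean_daily_min_temp_c=float(daily_min.mean()),
    )


def classify_year(yc: YearClimate, baseline: Baseline) -> YearClimate:
    """Assign wet/dry and warm/cold labels against the baseline.

    Wet iff total precipitation strictly exceeds precip_ratio x historical
    mean; warm iff mean daily minimum temperature strictly exceeds
    temp_ratio x historical mean (note both temperature quantities are
    negative Celsius values, so the threshold is e.g. 0.465 x (-6.4) =
    -2.976 C and "above" means warmer).  Values exactly at a threshold
    fall in the dry/cold category (unreachable in the study data).
    """
    precip_thresh = baseline.precip_ratio * baseline.historical_mean_precip_mm
    temp_thresh = baseline.temp_ratio * baseline.historical_mean_min_temp_c
    return replace(
        yc,
        wet_dry="wet" if yc.total_precip_mm > precip_thresh else "dry",
        warm_cold="warm" if yc.mean_daily_min_temp_c > temp_thresh else "cold",
    )


def derive_baseline_ratios(
    study_years: Sequence[YearClimate],
    historical_mean_precip_mm: float = HISTORICAL_MEAN_PRECIP_MM,
    historical_mean_min_temp_c: float = HISTORICAL_MEAN_MIN_TEMP_C,
) -> Baseline:
    """Derive the classification ratios from the study years themselves.

    The ratio is (study-period mean) / (historical mean) for each
    variable, i.e. the study mean expressed as a fraction of the
    1950--2000 mean.  With the published study years this gives ~0.718
    for precipitation and ~0.466 for minimum temperature.
    """
    if len(study_years) < 2:
        raise ValueError("need at least 2 study years")
    if historical_mean_precip_mm == 0 or historical_mean_min_temp_c == 0:
        raise ValueError("historical means must be nonzero")
    precip_mean = float(np.mean([y.total_precip_mm for y in study_years]))
    temp_mean = float(np.mean([y.mean_daily_min_temp_c for y in study_years]))
    return Baseline(
        historical_mean_precip_mm=historical_mean_precip_mm,
        historical_mean_min_temp_c=historical_mean_min_temp_c,
        precip_ratio=precip_mean / historical_mean_precip_mm,
        temp_ratio=temp_mean / historical_mean_min_temp_c,
    )


def correlation_screen(precip: Sequence[float],
                       temp: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation between yearly precipitation and temperature.

    Returns (r, two-sided p).  Run before treating the two variables as
    separate predictors; a strong correlation argues for separate model
    groups rather than a joint model.
    """
    precip = np.asarray(precip, dtype=float)
    temp = np.asarray(temp, dtype=float)
    if precip.shape != temp.shape or precip.size < 3:
        raise ValueError("need equal-length series with >= 3 values")
    if np.ptp(precip) == 0 or np.ptp(temp) == 0:
        raise ValueError("zero variance in input series")
    r, p = stats.pearsonr(precip, temp)
    return float(r), float(p)


def window_covariate(hourly: pd.DataFrame, season_year: int,
                     window: CovariateWindow) -> float:
    """Scalar covariate value for one year under one candidate window."""
    lo, hi = _window_bounds(season_year, window.start, window.end)
    win = _slice_window(hourly, lo, hi)
    if win.empty:
        raise ValueError(f"no data for {window.name} in year {season_year}")
    if window.variable == "precip_total":
        return float(win["precip_mm"].fillna(0).sum())
    temps = win.dropna(subset=["temp_c"])
    grp = temps.groupby(temps["timestamp"].dt.normalize())["temp_c"]
    daily = {"temp_mean": grp.mean(), "temp_min": grp.min(),
             "temp_max": grp.max()}[window.variable]
    return float(daily.mean())


def select_window_aic(counts: Sequence[int],
                      covariates: pd.DataFrame) -> pd.DataFrame:
    """Rank candidate yearly covariates by AIC of a Poisson regression.

    Each column of ``covariates`` is one candidate window's value attached
    to every delivery interval (one row per interval).  For each candidate
    a log-link Poisson GLM of the interval counts on that single scalar is
    fitted by maximum likelihood; candidates are returned sorted by AIC
    (= 2k - 2 lnL) with a ``delta_aic`` column.  Non-convergent fits get
    ``converged=False`` and AIC NaN instead of aborting the screen.
    """
    y = np.asarray(counts, dtype=float)
    if covariates.shape[1] < 1:
        raise ValueError("need at least one candidate window")
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    rows = []
    for name in covariates.columns:
        x = sm.add_constant(np.asarray(covariates[name], dtype=float))
        try:
            res = sm.GLM(y, x, family=sm.families.Poisson()).fit()
            rows.append({"window": name, "aic": float(res.aic),
                         "converged": bool(res.converged)})
        except Exception as exc:  # keep screening the other candidates
            logger.warning("window %s failed to fit: %s", name, exc)
            rows.append({"window": name, "aic": np.nan, "converged": False})
    out = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].min()
    return out
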