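"""Data model, CSV ingestion, and record-level filtering rules.

The field protocol behind these types: nests are watched for 15-minute
intervals within 90 minutes of sunset; every visit by an adult is one prey
delivery (the species carries one prey item per trip).  Deliveries are
attributed to the male or female from behavioural cues observed at the
moment of delivery; ambiguous deliveries stay "unknown".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "DeliveryObservation",
    "NestRecord",
    "MassRecord",
    "SexCues",
    "SchemaError",
    "ReadResult",
    "read_table",
    "attribute_sex",
    "filter_observations",
    "FilterResult",
    "exclude_unknown_fate",
    "check_stage_consistency",
]

# Fixed CSV schemas (comma-separated, UTF-8, ISO-8601 dates, '.' decimal,
# one header row).  Writers in other modules emit the same columns.
SCHEMAS: dict[str, list[str]] = {
    "deliveries": [
        "nest_id", "obs_date", "nest_age_days", "minutes_after_sunset",
        "interval_minutes", "n_male", "n_female", "n_unknown",
    ],
    "nests": ["nest_id", "year", "clutch", "brood", "fledglings", "fate_known"],
    "masses": ["band_id", "cohort", "obs_date", "julian_day",
               "nestling_age_days", "mass_g"],
    "weather_hourly": ["timestamp", "precip_mm", "temp_c"],
}


class SchemaError(ValueError):
    """Raised when a CSV is missing a required column for its schema."""


@dataclass(frozen=True)
class DeliveryObservation:
    """One 15-min nest watch with per-sex delivery counts.

    ``nest_age_days`` counts days since hatch (day 0 = hatch);
    ``minutes_after_sunset`` is the interval start time.
    """

    nest_id: str
    obs_date: date
    nest_age_days: int
    minutes_after_sunset: float
    interval_minutes: float
    n_male: int
    n_female: int
    n_unknown: int

    def __post_init__(self) -> None:
        if min(self.n_male, self.n_female, self.n_unknown) < 0:
            raise ValueError("delivery counts must be >= 0")
        if not self.interval_minutes > 0:
            raise ValueError("interval_minutes must be > 0")
        if self.nest_age_days < 0:
            raise ValueError("nest_age_days must be >= 0")
        if self.minutes_after_sunset < 0:
            raise ValueError("minutes_after_sunset must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_male + self.n_female + self.n_unknown


@dataclass(frozen=True)
class NestRecord:
    """Productivity record for one nest in one breeding year.

    ``clutch``/``brood``/``fledglings`` are stage-wise counts and may be
    missing (None) when a stage was not observed.  ``clutch >= brood >=
    fledglings`` is expected biologically but is *not* a constructor
    invariant (partial predation and abandonment are recorded stage-wise);
    ``check_stage_consistency`` flags violations.
    """

    nest_id: str
    year: int
    clutch: int | None
    brood: int | None
    fledglings: int | None
    fate_known: bool

    def __post_init__(self) -> None:
        for v in (self.clutch, self.brood, self.fledglings):
            if v is not None and v < 0:
                raise ValueError("stage counts must be >= 0")


@dataclass(frozen=True)
class MassRecord:
    """A single weighing of an adult or nestling, in grams."""

    band_id: str
    cohort: str  # adult_male | adult_female | nestling
    obs_date: date
    julian_day: int
    nestling_age_days: int | None
    mass_g: float

    _COHORTS = ("adult_male", "adult_female", "nestling")

    def __post_init__(self) -> None:
        if self.cohort not in self._COHORTS:
            raise ValueError(f"cohort must be one of {self._COHORTS}")
        if not self.mass_g > 0:
            raise ValueError("mass_g must be > 0")
        if (self.cohort == "nestling") != (self.nestling_age_days is not None):
            raise ValueError("nestling_age_days present iff cohort == nestling")


@dataclass(frozen=True)
class SexCues:
    """Behavioural cues observed at one delivery.

    Male-attribution cues: the female was known to be on the nest; male
    vocalizations accompanied the delivery; the female was heard vocalizing
    off-nest while a second owl entered the cavity.  The mirror cues
    attribute the delivery to the female.
    """

    female_on_nest: bool = False
    male_vocal_delivery: bool = False
    female_vocal_off_nest: bool = False
    male_on_nest: bool = False
    female_vocal_delivery: bool = False
    male_vocal_off_nest: bool = False


def attribute_sex(cues: SexCues) -> str:
    """Attribute one delivery to ``'male'``, ``'female'`` or ``'unknown'``.

    A delivery is male if any male criterion holds and female if any
    opposing criterion holds.  If cues for both sexes fire the delivery is
    conservatively ``'unknown'`` (the protocol never describes this case).
    """
    male = cues.female_on_nest or cues.male_vocal_delivery or cues.female_vocal_off_nest
    female = cues.male_on_nest or cues.female_vocal_delivery or cues.male_vocal_off_nest
    if male and not female:
        return "male"
    if female and not male:
        return "female"
    return "unknown"


@dataclass
class ReadResult:
    """Parsed records plus row-indexed messages for rejected rows.

    Iterates over the successfully parsed records so it can be used
    directly wherever a sequence of records is expected.
    """

    records: list
    errors: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def _parse_bool(v: str) -> bool:
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


def _opt_int(v) -> int | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
        return None
    return int(float(v))


def _row_to_record(kind: str, row: pd.Series):
    if kind == "deliveries":
        return DeliveryObservation(
            nest_id=str(row["nest_id"]),
            obs_date=date.fromisoformat(str(row["obs_date"])),
            nest_age_days=int(float(row["nest_age_days"])),
            minutes_after_sunset=float(row["minutes_after_sunset"]),
            interval_minutes=float(row["interval_minutes"]),
            n_male=int(float(row["n_male"])),
            n_female=int(float(row["n_female"])),
            n_unknown=int(float(row["n_unknown"])),
        )
    if kind == "nests":
        return NestRecord(
            nest_id=str(row["nest_id"]),
            year=int(float(row["year"])),
            clutch=_opt_int(row["clutch"]),
            brood=_opt_int(row["brood"]),
            fledglings=_opt_int(row["fledglings"]),
            fate_known=_parse_bool(row["fate_known"]),
        )
    if kind == "masses":
        return MassRecord(
            band_id=str(row["band_id"]),
            cohort=str(row["cohort"]).strip(),
            obs_date=date.fromisoformat(str(row["obs_date"])),
            julian_day=int(float(row["julian_day"])),
            nestling_age_days=_opt_int(row["nestling_age_days"]),
            mass_g=float(row["mass_g"]),
        )
    raise ValueError(f"unknown table kind: {kind!r}")


def read_table(path: str | Path, schema: str) -> ReadResult:
    """Read one of the fixed CSV schemas into typed records.

    Parameters
    ----------
    path:
        CSV file path.
    schema:
        One of ``'deliveries'``, ``'nests'``, ``'masses'``.

    Rows whose required fields do not parse are rejected individually;
    the messages (``"row <i>: <reason>"``, 0-based data-row index) are
    collected on the returned :class:`ReadResult`.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    SchemaError
        If a required column is absent, naming the column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if schema not in SCHEMAS or schema == "weather_hourly":
        raise ValueError(f"unknown record schema: {schema!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in SCHEMAS[schema]:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    records, errors = [], []
    for i, row in df.iterrows():
        try:
            records.append(_row_to_record(schema, row))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    return ReadResult(records=records, errors=errors)


def read_weather_hourly(path: str | Path) -> pd.DataFrame:
    """Read an hourly weather CSV (timestamp, precip_mm, temp_c)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, parse_dates=["timestamp"])
    for col in SCHEMAS["weather_hourly"]:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    return df


# --- observation filtering -------------------------------------------------

FULL_INTERVAL_MIN = 15.0
MAX_MINUTES_AFTER_SUNSET = 90.0
_TOL = 1e-9


@dataclass
class FilterResult:
    """Retained observations plus per-rule drop counts."""

    retained: list[DeliveryObservation]
    dropped: dict[str, int]

    def __iter__(self) -> Iterator[DeliveryObservation]:
        return iter(self.retained)

    def __len__(self) -> int:
        return len(self.retained)


def filter_observations(obs: Iterable[DeliveryObservation]) -> FilterResult:
    """Apply the interval-level inclusion rules.

    Retains intervals observed for the full 15 minutes that started no
    later than 90 minutes after sunset (the boundary itself is retained:
    only *later than* 90 min is dropped).  Intervals longer than 15 min
    are dropped with their own reason code rather than truncated.
    Idempotent by construction.
    """
    retained: list[DeliveryObservation] = []
    dropped = {"incomplete_interval": 0, "overlong_interval": 0, "late_after_sunset": 0}
    for o in obs:
        if o.interval_minutes < FULL_INTERVAL_MIN - _TOL:
            dropped["incomplete_interval"] += 1
        elif o.interval_minutes > FULL_INTERVAL_MIN + _TOL:
            dropped["overlong_interval"] += 1
        elif o.minutes_after_sunset > MAX_MINUTES_AFTER_SUNSET + _TOL:
            dropped["late_after_sunset"] += 1
        else:
            retained.append(o)
    return FilterResult(retained=retained, dropped=dropped)


def exclude_unknown_fate(
    nests: Sequence[NestRecord], obs: Sequence[DeliveryObservation]
) -> tuple[list[NestRecord], list[DeliveryObservation]]:
    """Drop unknown-fate nests from all analyses.

    Nests whose fate is unknown are removed from the productivity table
    and their delivery observations are removed as well.  Observations at
    known-fate nests are retained even when the nest later failed: the
    field protocol only records watches that preceded failure, so fate
    knowledge is the operative filter.  Observations whose nest has no
    productivity record are retained (no evidence of unknown fate).
    """
    unknown = {n.nest_id for n in nests if not n.fate_known}
    kept_nests = [n for n in nests if n.fate_known]
    kept_obs = [o for o in obs if o.nest_id not in unknown]
    return kept_nests, kept_obs


def write_table(records: Iterable, path: str | Path, schema: str) -> None:
    """Write records back out in the same fixed CSV schema they are read
    from, so pipeline stages compose through files."""
    if schema not in SCHEMAS or schema == "weather_hourly":
        raise ValueError(f"unknown record schema: {schema!r}")
    cols = SCHEMAS[schema]
    rows = []
    for r in records:
        row = {}
        for c in cols:
            v = getattr(r, c)
            row[c] = "" if v is None else v
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_weather_hourly(df: pd.DataFrame, path: str | Path) -> None:
    """Write an hourly weather frame in the fixed schema."""
    df[SCHEMAS["weather_hourly"]].to_csv(path, index=False)


def check_stage_consistency(nests: Iterable[NestRecord]) -> list[str]:
    """Flag nests where the stage counts increase (fledglings > brood etc.).

    Returns one message per violating nest; after this check passes (no
    messages), ``fledglings <= brood <= clutch`` holds wherever the stages
    are jointly observed.
    """
    msgs = []
    for n in nests:
        if n.clutch is not None and n.brood is not None and n.brood > n.clutch:
            msgs.append(f"nest {n.nest_id}: brood {n.brood} > clutch {n.clutch}")
        if n.brood is not None and n.fledglings is not None and n.fledglings > n.brood:
            msgs.append(
                f"nest {n.nest_id}: fledglings {n.fledglings} > brood {n.brood}"
            )
    return msgs
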