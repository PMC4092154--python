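"""Reading, filtering and cruise-level aggregation of survey records.

The analysis unit is the fishing cruise, not the individual set: sets
within a cruise are not independent samples, so catch and effort are
summed and environmental measurements averaged per cruise before any
modeling.  Drumline sets are excluded from abundance analyses (different
effort geometry), as is the initial survey period before the gear was
standardized (hooks suspended by floats), i.e. May 2004 through August
2005 inclusive.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from zicpue.errors import RowParseError, SchemaError, ValidationError

__all__ = [
    "ENV_COVARIATES",
    "SetRecord",
    "CaptureRecord",
    "CruiseSample",
    "read_set_table",
    "read_capture_table",
    "apply_standardization_filters",
    "aggregate_by_cruise",
    "cruises_to_frame",
    "write_cruise_table",
]

#: environmental covariates recorded per set, with their units:
#: temp degC, salin ups, visib m, tidamp m, pluvio mm, winddir deg [0, 360),
#: windspe m/s, solarrad kWh/m^2, lunday day-of-lunar-cycle in [1, 30]
ENV_COVARIATES = (
    "lunday",
    "temp",
    "salin",
    "visib",
    "tidamp",
    "pluvio",
    "winddir",
    "windspe",
    "solarrad",
)

SITES = ("BV", "PA", "CS")
GEARS = ("longline", "drumline")

# gear-standardization discard window, inclusive
DISCARD_START = dt.date(2004, 5, 1)
DISCARD_END = dt.date(2005, 8, 31)


def _normalize_species(name: str) -> str:
    """Lowercase binomial keys; anything unrecognizable passes through."""
    return " ".join(str(name).strip().lower().split())


@dataclass
class SetRecord:
    """One fishing set: a single gear deployment."""

    cruise_id: str
    date: dt.date
    site: str
    gear: str
    hooks: int
    catch: dict[str, int] = field(default_factory=dict)
    env: dict[str, float] = field(default_factory=dict)  # NaN == missing

    def __post_init__(self):
        if self.hooks <= 0:
            raise ValidationError(f"hooks must be positive, got {self.hooks}")
        self.catch = {_normalize_species(sp): c for sp, c in self.catch.items()}
        for sp, c in self.catch.items():
            if c < 0:
                raise ValidationError(f"negative catch for {sp!r}")
        wd = self.env.get("winddir")
        if wd is not None and not math.isnan(wd) and not (0 <= wd < 360):
            raise ValidationError(f"winddir out of [0, 360): {wd}")
        ld = self.env.get("lunday")
        if ld is not None and not math.isnan(ld) and not (1 <= ld <= 30):
            raise ValidationError(f"lunday out of [1, 30]: {ld}")


@dataclass
class CaptureRecord:
    """One captured shark: species, sex, stretched total length."""

    species: str
    sex: str  # "M", "F" or "unknown"
    tl_cm: float
    date: dt.date
    site: str

    def __post_init__(self):
        if self.tl_cm <= 0:
            raise ValidationError(f"tl_cm must be positive, got {self.tl_cm}")


@dataclass
class CruiseSample:
    """One aggregated fishing cruise: the analysis unit."""

    cruise_id: str
    site: str
    year: int
    month: float  # calendar month, continuous 1-12
    quarter: int
    effort_hooks: int
    count: dict[str, int] = field(default_factory=dict)
    env: dict[str, float] = field(default_factory=dict)


def _parse_date(value, row: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise RowParseError(f"row {row}: bad ISO date {value!r}", row) from exc


def _parse_number(value, row: int, what: str) -> float:
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan", "none"):
        return math.nan
    try:
        return float(s)
    except ValueError as exc:
        raise RowParseError(f"row {row}: non-numeric {what} {value!r}", row) from exc


def _read_delimited(path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delimiter = "\t" if sample.count("\t") > sample.count(",") else ","
        reader = csv.reader(fh, delimiter=delimiter)
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    if not rows:
        raise SchemaError(f"{path}: empty file")
    return [h.strip() for h in rows[0]], rows[1:]


def read_set_table(path, schema: dict | None = None) -> list[SetRecord]:
    """Read a delimited fishing-set table into SetRecords.

    Expected columns (renameable through ``schema``, a map from the
    standard name to the file's column name): cruise_id, date, site, gear,
    hooks, the environmental covariates of :data:`ENV_COVARIATES` (missing
    cells become NaN, never zero), and one column per species holding
    catch counts.  Any unrecognized column is treated as a species count
    column under its lowercase binomial key.
    """
    schema = schema or {}
    header, rows = _read_delimited(path)
    colmap = {schema.get(name, name): name for name in
              ("cruise_id", "date", "site", "gear", "hooks")}
    for std in ("cruise_id", "date", "site", "gear", "hooks"):
        file_col = schema.get(std, std)
        if file_col not in header:
            raise SchemaError(f"missing required column {file_col!r} (for {std})")
    env_cols = {schema.get(name, name): name for name in ENV_COVARIATES}
    idx = {name: header.index(name) for name in header}

    species_cols = [
        c for c in header if c not in colmap and c not in env_cols
    ]
    records = []
    for i, row in enumerate(rows, start=1):
        def cell(col):
            j = idx[col]
            return row[j] if j < len(row) else ""

        hooks_raw = _parse_number(cell(schema.get("hooks", "hooks")), i, "hooks")
        if math.isnan(hooks_raw) or hooks_raw != int(hooks_raw):
            raise RowParseError(f"row {i}: non-integer hooks", i)
        catch = {}
        for c in species_cols:
            v = _parse_number(cell(c), i, f"catch ({c})")
            if math.isnan(v):
                v = 0.0
            if v != int(v) or v < 0:
                raise RowParseError(f"row {i}: bad catch count {c!r}", i)
            catch[_normalize_species(c)] = int(v)
        env = {
            std: _parse_number(cell(file_col), i, std)
            for file_col, std in env_cols.items()
            if file_col in idx
        }
        records.append(
            SetRecord(
                cruise_id=str(cell(schema.get("cruise_id", "cruise_id"))).strip(),
                date=_parse_date(cell(schema.get("date", "date")), i),
                site=str(cell(schema.get("site", "site"))).strip(),
                gear=str(cell(schema.get("gear", "gear"))).strip().lower(),
                hooks=int(hooks_raw),
                catch=catch,
                env=env,
            )
        )
    return records


def read_capture_table(path, schema: dict | None = None) -> list[CaptureRecord]:
    """Read a delimited individual-capture table (species, sex, tl_cm, date, site)."""
    schema = schema or {}
    header, rows = _read_delimited(path)
    for std in ("species", "sex", "tl_cm", "date", "site"):
        if schema.get(std, std) not in header:
            raise SchemaError(f"missing required column {schema.get(std, std)!r}")
    idx = {name: header.index(name) for name in header}
    out = []
    for i, row in enumerate(rows, start=1):
        def cell(std):
            return row[idx[schema.get(std, std)]]

        sex = str(cell("sex")).strip().upper()
        if sex not in ("M", "F"):
            sex = "unknown"
        out.append(
            CaptureRecord(
                species=_normalize_species(cell("species")),
                sex=sex,
                tl_cm=_parse_number(cell("tl_cm"), i, "tl_cm"),
                date=_parse_date(cell("date"), i),
                site=str(cell("site")).strip(),
            )
        )
    return out


def apply_standardization_filters(sets: list[SetRecord]) -> list[SetRecord]:
    """Keep only sets usable for abundance analysis.

    Drumline sets are discarded, as are sets in the pre-standardization
    window May 2004 through August 2005 (inclusive).  Order is preserved.
    """
    return [
        s
        for s in sets
        if s.gear == "longline" and not (DISCARD_START <= s.date <= DISCARD_END)
    ]


def aggregate_by_cruise(sets: list[SetRecord]) -> list[CruiseSample]:
    """Aggregate sets into one CruiseSample per (cruise_id, site).

    Hooks and per-species catches are summed; each environmental covariate
    is averaged over its non-missing member values (missing only when all
    members are missing).  Cruise date is the earliest member date; month
    is its calendar month (continuous 1-12) and quarter = ceil(month / 3).
    A cruise whose sets span more than 7 days is rejected as mis-keyed.
    """
    groups: dict[tuple[str, str], list[SetRecord]] = {}
    order: list[tuple[str, str]] = []
    for s in sets:
        key = (s.cruise_id, s.site)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(s)

    out = []
    for key in order:
        members = groups[key]
        dates = [m.date for m in members]
        if (max(dates) - min(dates)).days > 7:
            raise ValidationError(
                f"cruise {key[0]!r} at {key[1]} spans more than 7 days; "
                "likely mis-keyed cruise_id"
            )
        date = min(dates)
        count: dict[str, int] = {}
        for m in members:
            for sp, c in m.catch.items():
                count[sp] = count.get(sp, 0) + c
        env: dict[str, float] = {}
        for name in ENV_COVARIATES:
            vals = [
                m.env[name]
                for m in members
                if name in m.env and not math.isnan(m.env[name])
            ]
            env[name] = float(np.mean(vals)) if vals else math.nan
        month = float(date.month)
        out.append(
            CruiseSample(
                cruise_id=key[0],
                site=key[1],
                year=date.year,
                month=month,
                quarter=int(math.ceil(month / 3.0)),
                effort_hooks=sum(m.hooks for m in members),
                count=count,
                env=env,
            )
        )
    return out


def cruises_to_frame(cruises: list[CruiseSample]) -> pd.DataFrame:
    """Flatten CruiseSamples into the modeling table.

    Columns: cruise_id, site, year, month, quarter, effort_hooks, the
    environmental covariates, and one ``count_<species>`` column per
    species seen anywhere in the input.
    """
    species = sorted({sp for c in cruises for sp in c.count})
    rows = []
    for c in cruises:
        row = {
            "cruise_id": c.cruise_id,
            "site": c.site,
            "year": c.year,
            "month": c.month,
            "quarter": c.quarter,
            "effort_hooks": c.effort_hooks,
        }
        row.update({name: c.env.get(name, math.nan) for name in ENV_COVARIATES})
        row.update({f"count_{sp}": c.count.get(sp, 0) for sp in species})
        rows.append(row)
    return pd.DataFrame(rows)


def write_cruise_table(cruises, path, delimiter: str = ",") -> None:
    """Write the aggregated cruise table as delimited text."""
    frame = cruises if isinstance(cruises, pd.DataFrame) else cruises_to_frame(cruises)
    frame.to_csv(path, sep=delimiter, index=False)
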