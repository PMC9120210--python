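"""CSV schemas and packaged literature tables.

Two study-level tables are bundled with the package, transcribed from the
published literature compilation on roe deer offspring sex ratios:

* the *reference table* (25 rows): proportion female, exact 95% CI, sample
  size, country, living condition and ratio type (prenatal P / secondary S)
  per reference;
* the *site table* (15 rows): the secondary-sex-ratio data sets with WGS84
  coordinates per study site.

Both tables print proportions to two decimals; integer counts are recovered
on load via :func:`capreosex.core_stats.counts_from_proportion`.  Note two
internal inconsistencies of the published tables, carried verbatim: the
printed site-table total (23,053) is less than the sum of its sample-size
column (23,420), so totals are always recomputed from rows; and the largest
German data set is printed as N = 12,473 in the tables while the prose
reports 12,437.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .core_stats import SexRatioCount, counts_from_proportion
from .meta_analysis import StudyRecord

__all__ = [
    "read_study_table",
    "write_study_table",
    "load_reference_table",
    "load_site_table",
    "read_offspring_table",
    "read_weather_table",
]

_REQUIRED = ("id", "pf", "n")
_OPTIONAL_FLOAT = ("latitude", "longitude", "ci_low", "ci_high")


class StudyTableError(ValueError):
    """Malformed study-table CSV; message names the column and line."""


def _parse_row(row: dict, line: int) -> StudyRecord:
    def bad(column: str, detail: str) -> StudyTableError:
        return StudyTableError(f"line {line}, column {column!r}: {detail}")

    for col in _REQUIRED:
        if row.get(col) in (None, ""):
            raise bad(col, "missing value")
    try:
        pf = float(row["pf"])
    except ValueError:
        raise bad("pf", f"not a number: {row['pf']!r}") from None
    if not 0.0 <= pf <= 1.0:
        raise bad("pf", f"proportion out of [0, 1]: {pf}")
    try:
        n = int(row["n"])
    except ValueError:
        raise bad("n", f"not an integer: {row['n']!r}") from None
    if n < 1:
        raise bad("n", f"sample size must be >= 1, got {n}")
    if row.get("n_female") not in (None, ""):
        try:
            n_female = int(row["n_female"])
        except ValueError:
            raise bad("n_female", f"not an integer: {row['n_female']!r}") from None
        if not 0 <= n_female <= n:
            raise bad("n_female", f"count out of [0, n]: {n_female}")
        counts = SexRatioCount(n_female=n_female, n_male=n - n_female)
    else:
        counts = counts_from_proportion(pf, n)
    floats: dict[str, Optional[float]] = {}
    for col in ("latitude", "longitude"):
        raw = row.get(col)
        if raw in (None, ""):
            floats[col] = None
        else:
            try:
                floats[col] = float(raw)
            except ValueError:
                raise bad(col, f"not a number: {raw!r}") from None
    try:
        return StudyRecord(
            id=str(row["id"]),
            reference_id=str(row.get("reference_id") or row["id"]),
            counts=counts,
            country=str(row.get("country") or ""),
            location=str(row.get("location") or ""),
            latitude=floats["latitude"],
            longitude=floats["longitude"],
            living_condition=str(row.get("living_condition") or ""),
            ratio_type=str(row.get("ratio_type") or ""),
            source=str(row.get("source") or ""),
        )
    except ValueError as exc:
        raise StudyTableError(f"line {line}: {exc}") from None


def read_study_table(path) -> list[StudyRecord]:
    """Read and validate a study-table CSV into StudyRecords.

    Requires columns ``id``, ``pf``, ``n``; uses ``n_female`` when present,
    otherwise reconstructs counts from the rounded proportion.  Malformed
    rows are reported with their line number.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise StudyTableError(f"{path}: empty file (no header)")
        missing = [c for c in _REQUIRED if c not in reader.fieldnames]
        if missing:
            raise StudyTableError(f"{path}: missing required columns {missing}")
        records = [_parse_row(row, line) for line, row in enumerate(reader, start=2)]
    if not records:
        raise StudyTableError(f"{path}: no data rows")
    return records


def write_study_table(studies: Sequence[StudyRecord], path) -> None:
    """Write StudyRecords as CSV; explicit counts make the round trip exact."""
    cols = [
        "id", "reference_id", "pf", "n_female", "n", "country", "location",
        "latitude", "longitude", "living_condition", "ratio_type", "source",
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for s in studies:
            writer.writerow(
                {
                    "id": s.id,
                    "reference_id": s.reference_id,
                    "pf": f"{s.counts.pf:.6f}",
                    "n_female": s.counts.n_female,
                    "n": s.counts.n_total,
                    "country": s.country,
                    "location": s.location,
                    "latitude": "" if s.latitude is None else s.latitude,
                    "longitude": "" if s.longitude is None else s.longitude,
                    "living_condition": s.living_condition,
                    "ratio_type": s.ratio_type,
                    "source": s.source,
                }
            )


def _packaged(name: str) -> list[StudyRecord]:
    with resources.as_file(resources.files("capreosex").joinpath("data", name)) as p:
        return read_study_table(p)


def load_reference_table() -> list[StudyRecord]:
    """The bundled 25-row reference-level table (prenatal and secondary)."""
    return _packaged("table2.csv")


def load_site_table() -> list[StudyRecord]:
    """The bundled 15-row secondary-sex-ratio site table with coordinates."""
    return _packaged("table3.csv")


def read_offspring_table(path) -> pd.DataFrame:
    """Offspring CSV: site_id, year, sex, elevation_m, est_age_days."""
    df = pd.read_csv(path)
    required = {"year", "sex", "elevation_m"}
    missing = required - set(df.columns)
    if missing:
        raise StudyTableError(f"{path}: missing offspring columns {sorted(missing)}")
    if not df["sex"].isin([0, 1]).all():
        raise StudyTableError(f"{path}: sex must be coded 0 (male) / 1 (female)")
    if (df["elevation_m"] < 0).any():
        raise StudyTableError(f"{path}: negative elevations present")
    return df


def read_weather_table(path) -> pd.DataFrame:
    """Weather CSV: year, month, temperature_c, precipitation_mm."""
    df = pd.read_csv(path)
    required = {"year", "month"}
    missing = required - set(df.columns)
    if missing:
        raise StudyTableError(f"{path}: missing weather columns {sorted(missing)}")
    if not df["month"].between(1, 12).all():
        raise StudyTableError(f"{path}: month values must lie in 1..12")
    if df.duplicated(subset=["year", "month"]).any():
        raise StudyTableError(f"{path}: duplicate (year, month) rows")
    return df
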