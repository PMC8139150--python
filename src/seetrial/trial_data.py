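"""Subject-level trial tables, per-unit event counts and region maps.

A trial is carried as a pandas DataFrame with one row per subject and a
fixed schema (:data:`SUBJECT_COLUMNS`): unit labels (country, site), a
binary treatment arm, and three time-to-event pairs — the composite
surrogate endpoint (first MACE: non-fatal stroke, non-fatal myocardial
infarction or CV death) and the two true endpoints (CV death, all-cause
death). Times are in years; event indicators are 0/1 integers.

Because CV death is a component of the composite, records must satisfy the
composite-dominance constraints: a CV death implies an all-cause death at
the same time, and a composite event no later than the CV death.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from ._leader import BUILTIN_REGION_MAPS

#: Column order of the subject-level CSV schema.
SUBJECT_COLUMNS = [
    "subject_id", "country", "site_id", "arm",
    "t_surrogate", "e_surrogate",
    "t_true_cv", "e_true_cv",
    "t_true_all", "e_true_all",
]

_TIME_COLUMNS = ["t_surrogate", "t_true_cv", "t_true_all"]
_EVENT_COLUMNS = ["e_surrogate", "e_true_cv", "e_true_all"]

#: Endpoint name -> (time column, event column).
ENDPOINT_COLUMNS: dict[str, tuple[str, str]] = {
    "surrogate": ("t_surrogate", "e_surrogate"),
    "cv_death": ("t_true_cv", "e_true_cv"),
    "all_cause_death": ("t_true_all", "e_true_all"),
}

TRUE_ENDPOINTS = ("cv_death", "all_cause_death")
UNITS = ("country", "site", "region")

COUNT_COLUMNS = ["unit_label", "n_subjects", "n_surrogate_events",
                 "n_true_events"]


class SubjectTableError(ValueError):
    """A subject table violates the schema or a record-level invariant."""


@dataclasses.dataclass(frozen=True)
class RegionMap:
    """Assignment of countries to geographical regions.

    ``mapping`` sends an ISO 3166-1 alpha-2 country code to a region label;
    every country present in a subject table must appear exactly once.
    """

    name: str
    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("region map is empty")

    @property
    def regions(self) -> list[str]:
        """Distinct region labels, in first-appearance order."""
        return list(dict.fromkeys(self.mapping.values()))

    def region_of(self, country: str) -> str:
        try:
            return self.mapping[country]
        except KeyError:
            raise KeyError(
                f"country {country!r} missing from region map {self.name!r}"
            ) from None


def load_region_map(source: str | Path) -> RegionMap:
    """Load a region map from a builtin name or a YAML/key-value file.

    Builtin names ``approach1``/``approach2``/``approach3`` are the three
    published groupings of the 32 LEADER countries (4, 7 and 10 regions).
    A file must parse to a flat mapping of country code to region label.
    """
    key = str(source)
    if key in BUILTIN_REGION_MAPS:
        return RegionMap(name=key, mapping=dict(BUILTIN_REGION_MAPS[key]))
    path = Path(source)
    if not path.exists():
        raise ValueError(
            f"unknown builtin region map {key!r} "
            f"(builtins: {sorted(BUILTIN_REGION_MAPS)}) and no such file"
        )
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SubjectTableError(f"region map file {path} is not a flat mapping")
    mapping: dict[str, str] = {}
    for country, region in raw.items():
        c = str(country)
        if c in mapping:
            raise SubjectTableError(f"duplicate country key {c!r} in {path}")
        mapping[c] = str(region)
    return RegionMap(name=path.stem, mapping=mapping)


def validate_subjects(subjects: pd.DataFrame) -> pd.DataFrame:
    """Validate a subject table against the schema and record invariants.

    Returns the table with canonical column order and dtypes. Raises
    :class:`SubjectTableError` naming the first offending row (0-based
    data row) and the violated rule.
    """
    missing = [c for c in SUBJECT_COLUMNS if c not in subjects.columns]
    if missing:
        raise SubjectTableError(f"missing column(s): {', '.join(missing)}")
    df = subjects[SUBJECT_COLUMNS].copy()

    for col in _TIME_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise SubjectTableError(f"row {row}: non-numeric value in {col!r}")
        df[col] = vals.astype(float)
    for col in _EVENT_COLUMNS + ["arm"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~vals.isin([0, 1])
        if bad.any():
            row = int(bad.idxmax())
            raise SubjectTableError(f"row {row}: {col!r} must be 0 or 1")
        df[col] = vals.astype(int)

    nonpos = ~np.isfinite(df[_TIME_COLUMNS]).all(axis=1) | (
        df[_TIME_COLUMNS] <= 0
    ).any(axis=1)
    if nonpos.any():
        row = int(nonpos.idxmax())
        raise SubjectTableError(
            f"row {row}: follow-up times must be strictly positive and finite"
        )

    cv = df["e_true_cv"] == 1
    bad = cv & ((df["e_true_all"] != 1) | (df["t_true_all"] != df["t_true_cv"]))
    if bad.any():
        row = int(bad.idxmax())
        raise SubjectTableError(
            f"row {row}: CV death must imply all-cause death at the same time "
            "(e_true_cv=1 requires e_true_all=1 and t_true_all == t_true_cv)"
        )
    bad = cv & ((df["e_surrogate"] != 1) | (df["t_surrogate"] > df["t_true_cv"]))
    if bad.any():
        row = int(bad.idxmax())
        raise SubjectTableError(
            f"row {row}: CV death is a composite component "
            "(e_true_cv=1 requires e_surrogate=1 and t_surrogate <= t_true_cv)"
        )
    return df


def read_subjects(path: str | Path) -> pd.DataFrame:
    """Read and validate a subject-level CSV (see :data:`SUBJECT_COLUMNS`)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "country": str,
                                  "site_id": str})
    return validate_subjects(df)


def write_subjects(subjects: pd.DataFrame, path: str | Path) -> None:
    """Write a validated subject table as UTF-8 CSV with the canonical header."""
    validate_subjects(subjects).to_csv(path, index=False)


def _unit_labels(subjects: pd.DataFrame, unit: str,
                 region_map: RegionMap | None) -> pd.Series:
    if unit == "country":
        return subjects["country"]
    if unit == "site":
        return subjects["site_id"]
    if unit == "region":
        if region_map is None:
            raise ValueError("unit='region' requires a region_map")
        countries = subjects["country"]
        unknown = set(countries.unique()) - set(region_map.mapping)
        if unknown:
            raise KeyError(
                f"countries absent from region map {region_map.name!r}: "
                f"{sorted(unknown)}"
            )
        return countries.map(region_map.mapping)
    raise ValueError(f"unknown unit {unit!r}; expected one of {UNITS}")


def count_events_by_unit(
    subjects: pd.DataFrame,
    unit: str = "country",
    true_endpoint: str = "cv_death",
    region_map: RegionMap | None = None,
) -> pd.DataFrame:
    """Tabulate subjects, surrogate events and true-endpoint events per unit.

    Parameters
    ----------
    subjects
        Validated subject table.
    unit
        ``country``, ``site`` or ``region`` (the latter requires
        ``region_map``).
    true_endpoint
        ``cv_death`` or ``all_cause_death`` — which endpoint fills the
        ``n_true_events`` column.

    Returns
    -------
    DataFrame with columns ``unit_label, n_subjects, n_surrogate_events,
    n_true_events``, one row per distinct unit, sorted by label; per-column
    sums equal the trial totals.
    """
    if true_endpoint not in TRUE_ENDPOINTS:
        raise ValueError(
            f"unknown true endpoint {true_endpoint!r}; expected one of "
            f"{TRUE_ENDPOINTS}"
        )
    subjects = validate_subjects(subjects)
    _, e_true = ENDPOINT_COLUMNS[true_endpoint]
    labels = _unit_labels(subjects, unit, region_map)
    grouped = (
        pd.DataFrame({
            "unit_label": labels,
            "n_subjects": 1,
            "n_surrogate_events": subjects["e_surrogate"],
            "n_true_events": subjects[e_true],
        })
        .groupby("unit_label", as_index=False, sort=True)
        .sum()
    )
    return grouped[COUNT_COLUMNS]


def read_unit_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-unit count CSV (``unit_label,n_subjects,...``)."""
    df = pd.read_csv(path, dtype={"unit_label": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise SubjectTableError(f"missing column(s): {', '.join(missing)}")
    df = df[COUNT_COLUMNS].copy()
    for col in COUNT_COLUMNS[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any() or (vals % 1 != 0).any():
            raise SubjectTableError(f"{col!r} must be nonnegative integers")
        df[col] = vals.astype(int)
    bad = df["n_surrogate_events"] > df["n_subjects"]
    bad |= df["n_true_events"] > df["n_subjects"]
    if bad.any():
        raise SubjectTableError(
            f"row {int(bad.idxmax())}: event count exceeds subject count"
        )
    return df


def write_unit_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts[COUNT_COLUMNS].to_csv(path, index=False)


def concat_subjects(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate subject tables, revalidating the result."""
    return validate_subjects(pd.concat(list(tables), ignore_index=True))
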