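"""Simplified OMOP-style data model: typed tables, delimited I/O, validation.

The model keeps five tables with OMOP CDM names and snake_case columns
(person, observation_period, visit_occurrence, condition_occurrence,
drug_exposure). Dates are calendar dates; all interval arithmetic downstream
is in whole days. Events dated outside a person's observation periods are
retained on load but flagged by the validator and ignored by cohort logic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "DateParseError",
    "ConceptSet",
    "Dataset",
    "Violation",
    "ValidationReport",
    "TABLE_SCHEMAS",
    "hs_concept_set",
    "read_concept_set",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "write_cohort",
    "read_cohort",
]

SEXES = ("female", "male", "unknown")
VISIT_TYPES = ("inpatient", "outpatient", "emergency", "none")

#: Diagnosis concepts for hidradenitis suppurativa: the SNOMED-mapped concept
#: for "hidradenitis suppurativa" (ICD-10 L73.2) and the older "hidradenitis"
#: concept (ICD-9 705.83). No vocabulary-hierarchy expansion is performed.
HS_SUPPURATIVA_CONCEPT = 4241223
HIDRADENITIS_CONCEPT = 434119

# table name -> (required columns, date columns)
TABLE_SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "person": (("person_id", "sex", "year_of_birth"), ()),
    "observation_period": (
        ("person_id", "observation_period_start_date", "observation_period_end_date"),
        ("observation_period_start_date", "observation_period_end_date"),
    ),
    "visit_occurrence": (
        ("person_id", "visit_start_date", "visit_type"),
        ("visit_start_date",),
    ),
    "condition_occurrence": (
        ("person_id", "condition_concept_id", "condition_start_date"),
        ("condition_start_date",),
    ),
    "drug_exposure": (
        ("person_id", "drug_concept_id", "drug_exposure_start_date"),
        ("drug_exposure_start_date",),
    ),
}


class SchemaError(ValueError):
    """A table is missing a required column."""


class DateParseError(ValueError):
    """A date cell could not be parsed; carries the offending line number."""


@dataclass(frozen=True)
class ConceptSet:
    """A named, flat set of vocabulary concept identifiers."""

    name: str
    concept_ids: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "concept_ids", frozenset(int(c) for c in self.concept_ids))
        if not self.concept_ids:
            raise ValueError(f"concept set {self.name!r} is empty")

    def __contains__(self, concept_id: int) -> bool:
        return int(concept_id) in self.concept_ids

    def union(self, extra: Iterable[int]) -> "ConceptSet":
        return ConceptSet(self.name, self.concept_ids | {int(c) for c in extra})


def hs_concept_set(extra: Iterable[int] = ()) -> ConceptSet:
    """The shipped hidradenitis suppurativa concept set, optionally extended."""
    return ConceptSet(
        "hidradenitis suppurativa",
        frozenset({HS_SUPPURATIVA_CONCEPT, HIDRADENITIS_CONCEPT}) | {int(c) for c in extra},
    )


def read_concept_set(path: str | Path, name: str | None = None) -> ConceptSet:
    """Read a concept set from a 2-column CSV (concept_id, concept_name)."""
    df = pd.read_csv(path)
    if "concept_id" not in df.columns:
        raise SchemaError(f"concept set file {path}: missing required column 'concept_id'")
    return ConceptSet(name or Path(path).stem, frozenset(df["concept_id"].astype(int)))


@dataclass
class Dataset:
    """In-memory collection of the five OMOP-style tables (pandas DataFrames)."""

    person: pd.DataFrame
    observation_period: pd.DataFrame
    visit_occurrence: pd.DataFrame = field(default_factory=pd.DataFrame)
    condition_occurrence: pd.DataFrame = field(default_factory=pd.DataFrame)
    drug_exposure: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        for name in TABLE_SCHEMAS:
            df = getattr(self, name)
            if df is None or (df.empty and not len(df.columns)):
                cols, dates = TABLE_SCHEMAS[name]
                empty = pd.DataFrame({c: pd.Series(dtype="datetime64[ns]" if c in dates else "object") for c in cols})
                setattr(self, name, empty)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_SCHEMAS}

    def events(self, domains: Iterable[str] = ("condition", "drug")) -> pd.DataFrame:
        """Unified clinical-event view: person_id, concept_id, event_date, domain."""
        frames = []
        if "condition" in domains and len(self.condition_occurrence):
            frames.append(
                self.condition_occurrence.rename(
                    columns={"condition_concept_id": "concept_id", "condition_start_date": "event_date"}
                )[["person_id", "concept_id", "event_date"]].assign(domain="condition")
            )
        if "drug" in domains and len(self.drug_exposure):
            frames.append(
                self.drug_exposure.rename(
                    columns={"drug_concept_id": "concept_id", "drug_exposure_start_date": "event_date"}
                )[["person_id", "concept_id", "event_date"]].assign(domain="drug")
            )
        if not frames:
            return pd.DataFrame(
                {
                    "person_id": pd.Series(dtype="object"),
                    "concept_id": pd.Series(dtype="int64"),
                    "event_date": pd.Series(dtype="datetime64[ns]"),
                    "domain": pd.Series(dtype="object"),
                }
            )
        return pd.concat(frames, ignore_index=True)

    def n_persons(self) -> int:
        return len(self.person)


def _check_columns(table: str, df: pd.DataFrame) -> None:
    required, _ = TABLE_SCHEMAS[table]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r}: missing required column(s) {', '.join(repr(c) for c in missing)}")


def _parse_dates(table: str, df: pd.DataFrame) -> pd.DataFrame:
    _, date_cols = TABLE_SCHEMAS[table]
    for col in date_cols:
        parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            # +2: header row plus 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise DateParseError(
                f"table {table!r}, column {col!r}: unparseable date {df[col][bad].iloc[0]!r} at line {line}"
            )
        df[col] = parsed
    return df


def read_table(table: str, path: str | Path) -> pd.DataFrame:
    """Read and type-check a single OMOP-style table from CSV."""
    if table not in TABLE_SCHEMAS:
        raise KeyError(f"unknown table {table!r}")
    df = pd.read_csv(path)
    _check_columns(table, df)
    return _parse_dates(table, df)


def read_dataset(paths: Mapping[str, str | Path] | str | Path) -> Dataset:
    """Load a dataset from a table-name -> file-path map, or from a directory
    containing files named ``<table>.csv``.

    Tables absent from the map (other than person and observation_period)
    load as empty.
    """
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        paths = {t: root / f"{t}.csv" for t in TABLE_SCHEMAS if (root / f"{t}.csv").exists()}
    loaded: dict[str, pd.DataFrame] = {}
    for table in ("person", "observation_period"):
        if table not in paths:
            raise FileNotFoundError(f"required table {table!r} not supplied")
    for table, path in paths.items():
        loaded[table] = read_table(table, path)
    return Dataset(**loaded)


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write all five tables as ``<table>.csv`` with ISO-8601 dates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for table, df in ds.tables().items():
        path = out / f"{table}.csv"
        _write_iso(df, path)
        written[table] = path
    return written


def _write_iso(df: pd.DataFrame, path: Path) -> None:
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_datetime64_any_dtype(df[col]):
            df[col] = df[col].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    rule: str
    count: int
    examples: tuple = ()


@dataclass
class ValidationReport:
    violations: list[Violation]

    @property
    def ok(self) -> bool:
        return not self.violations

    def count(self, rule: str) -> int:
        return sum(v.count for v in self.violations if v.rule == rule)

    def __iter__(self):
        return iter(self.violations)


def _in_observation_mask(events: pd.DataFrame, periods: pd.DataFrame, date_col: str) -> np.ndarray:
    """Boolean mask: each event date falls inside one of its person's periods."""
    if events.empty:
        return np.zeros(0, dtype=bool)
    ev = events[["person_id", date_col]].reset_index(drop=True).reset_index(names="_row")
    merged = ev.merge(
        periods[["person_id", "observation_period_start_date", "observation_period_end_date"]],
        on="person_id",
        how="left",
    )
    inside = (
        (merged[date_col] >= merged["observation_period_start_date"])
        & (merged[date_col] <= merged["observation_period_end_date"])
    ).fillna(False)
    mask = np.zeros(len(events), dtype=bool)
    mask[merged.loc[inside, "_row"].unique()] = True
    return mask


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Report structural violations without mutating the data.

    Checks: duplicate person_ids; implausible year_of_birth; overlapping
    observation periods within a person; period start after end; clinical
    events dated outside every observation period of their person; events or
    periods referencing unknown person_ids.
    """
    violations: list[Violation] = []
    persons = ds.person
    known = set(persons["person_id"])

    dup = persons["person_id"][persons["person_id"].duplicated()]
    if len(dup):
        violations.append(Violation("duplicate person_id", len(dup), tuple(dup.head(5))))

    yob = pd.to_numeric(persons["year_of_birth"], errors="coerce")
    bad_yob = persons.loc[(yob < 1900) | (yob > pd.Timestamp.now().year) | yob.isna(), "person_id"]
    if len(bad_yob):
        violations.append(Violation("year_of_birth out of range", len(bad_yob), tuple(bad_yob.head(5))))

    op = ds.observation_period
    rev = op["observation_period_start_date"] > op["observation_period_end_date"]
    if rev.any():
        violations.append(
            Violation("observation period start after end", int(rev.sum()), tuple(op.loc[rev, "person_id"].head(5)))
        )

    n_overlap = 0
    overlap_people = []
    for pid, grp in op.sort_values("observation_period_start_date").groupby("person_id"):
        starts = grp["observation_period_start_date"].to_numpy()
        ends = grp["observation_period_end_date"].to_numpy()
        hits = int((starts[1:] <= ends[:-1]).sum())
        if hits:
            n_overlap += hits
            overlap_people.append(pid)
    if n_overlap:
        violations.append(Violation("overlapping observation periods", n_overlap, tuple(overlap_people[:5])))

    for table, date_col in (
        ("visit_occurrence", "visit_start_date"),
        ("condition_occurrence", "condition_start_date"),
        ("drug_exposure", "drug_exposure_start_date"),
    ):
        df = getattr(ds, table)
        if df.empty:
            continue
        unknown = ~df["person_id"].isin(known)
        if unknown.any():
            violations.append(
                Violation(f"{table}: unknown person_id", int(unknown.sum()), tuple(df.loc[unknown, "person_id"].head(5)))
            )
        inside = _in_observation_mask(df, op, date_col)
        outside = int((~inside).sum())
        if outside:
            violations.append(Violation(f"{table}: event outside observation", outside))

    unknown_op = ~op["person_id"].isin(known)
    if unknown_op.any():
        violations.append(
            Violation("observation_period: unknown person_id", int(unknown_op.sum()), tuple(op.loc[unknown_op, "person_id"].head(5)))
        )
    return ValidationReport(violations)


# ---------------------------------------------------------------------------
# cohort I/O (cohort objects live in phenoforge.cohorts; I/O is plain tables)

COHORT_COLUMNS = ("cohort_id", "person_id", "cohort_start_date", "cohort_end_date")


def write_cohort(cohort, path: str | Path) -> Path:
    """Write a cohort as CSV (cohort_id, person_id, cohort_start_date, cohort_end_date)."""
    path = Path(path)
    df = cohort.table.copy()
    df.insert(0, "cohort_id", cohort.cohort_id)
    _write_iso(df[list(COHORT_COLUMNS)], path)
    return path


def read_cohort(path: str | Path):
    """Read a cohort written by :func:`write_cohort` (inverse round trip)."""
    from .cohorts import Cohort  # local import to avoid a cycle

    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path}: missing required column(s) {missing}")
    for col in ("cohort_start_date", "cohort_end_date"):
        df[col] = pd.to_datetime(df[col], format="ISO8601")
    cohort_id = df["cohort_id"].iloc[0] if len(df) else Path(path).stem
    return Cohort(cohort_id=cohort_id, table=df[["person_id", "cohort_start_date", "cohort_end_date"]])
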