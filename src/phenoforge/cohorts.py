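"""Phenotype-algorithm cohort engine.

A :class:`CohortDefinition` declares the temporal logic of a phenotype
algorithm: a diagnosis concept set, whether entry must be the first-ever
qualifying code (incident), a continuous-enrollment washout before entry,
and an optional requirement for confirmation codes inside a day window
after the entry code. Executing a definition against a dataset yields a
:class:`Cohort` of (person, index date) rows.

The four standard hidradenitis suppurativa algorithms are:

====================  ========  ============  ==============  ====================
name                  incident  washout_days  min_code_count  confirmation_window
====================  ========  ============  ==============  ====================
incident_1x           yes       365           1               --
incident_2x           yes       365           2               [31, 365]
prevalent_1x          no        0             1               --
prevalent_2x          no        0             2               [31, 365]
====================  ========  ============  ==============  ====================

Semantics, fixed here once and used everywhere:

* Only condition-domain events whose concept is in the definition's concept
  set and whose date lies inside one of the person's observation periods
  qualify. Same-day duplicates collapse to a single qualifying day: a single
  encounter must not confirm itself.
* Incident: the candidate entry is the person's first-ever qualifying day
  across all observation periods. It must have at least ``washout_days`` of
  continuous observation before it within its own observation period.
  If the first-ever code fails washout or confirmation the person is
  excluded entirely (not deferred to a later code) — that is what makes the
  cohort incident.
* Confirmation: with ``min_code_count`` = N >= 2, at least N-1 additional
  qualifying days must fall within ``confirmation_window`` = [low, high]
  days after the entry day (both endpoints inclusive), inside the same
  observation period as the entry.
* Prevalent: the entry is the earliest qualifying day that satisfies the
  washout (trivially, with washout 0) and confirmation requirements.
* Index date is the entry day by default (``index_at="first"``); with
  ``index_at="confirmation"`` it is the day the last required confirmation
  code arrives. Cohort exit is the end of the observation period containing
  the entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_model import ConceptSet, Dataset, hs_concept_set

__all__ = [
    "CohortDefinition",
    "Cohort",
    "qualifying_events",
    "build_cohort",
    "hs_definitions",
    "build_hs_suite",
    "code_count_ladder",
]


@dataclass(frozen=True)
class CohortDefinition:
    """Declarative entry/washout/confirmation logic for a phenotype algorithm."""

    name: str
    concept_set: ConceptSet
    incident: bool = False
    washout_days: int = 0
    min_code_count: int = 1
    confirmation_window: tuple[int, int] = (31, 365)
    index_at: str = "first"

    def __post_init__(self) -> None:
        low, high = self.confirmation_window
        if self.washout_days < 0:
            raise ValueError("washout_days must be >= 0")
        if self.min_code_count < 1:
            raise ValueError("min_code_count must be >= 1")
        if low < 1 or high < low:
            raise ValueError("confirmation_window must satisfy 1 <= low <= high")
        if self.index_at not in ("first", "confirmation"):
            raise ValueError("index_at must be 'first' or 'confirmation'")


@dataclass
class Cohort:
    """(person, index date, exit date) rows produced by one definition.

    At most one row per person; index dates lie inside an observation period
    of the source dataset.
    """

    cohort_id: str
    table: pd.DataFrame  # person_id, cohort_start_date, cohort_end_date

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, person_id) -> bool:
        return person_id in self.person_ids

    @property
    def person_ids(self) -> set:
        return set(self.table["person_id"])

    def index_dates(self) -> pd.Series:
        """person_id -> index date."""
        return self.table.set_index("person_id")["cohort_start_date"]

    def restrict(self, persons: Iterable) -> "Cohort":
        keep = self.table["person_id"].isin(set(persons))
        return Cohort(self.cohort_id, self.table.loc[keep].reset_index(drop=True))


_EMPTY_COHORT_COLS = {
    "person_id": pd.Series(dtype="object"),
    "cohort_start_date": pd.Series(dtype="datetime64[ns]"),
    "cohort_end_date": pd.Series(dtype="datetime64[ns]"),
}


def qualifying_events(ds: Dataset, cs: ConceptSet) -> pd.DataFrame:
    """Condition events in the concept set, inside observation, date-sorted.

    Returns columns person_id, event_date, concept_id sorted ascending by
    (person_id, event_date) with stable ties broken by concept_id. Events
    dated outside every observation period of their person are dropped.
    """
    cond = ds.condition_occurrence
    if cond.empty:
        return pd.DataFrame(
            {
                "person_id": pd.Series(dtype="object"),
                "event_date": pd.Series(dtype="datetime64[ns]"),
                "concept_id": pd.Series(dtype="int64"),
            }
        )
    hit = cond[cond["condition_concept_id"].isin(cs.concept_ids)]
    ev = hit.rename(columns={"condition_start_date": "event_date", "condition_concept_id": "concept_id"})[
        ["person_id", "event_date", "concept_id"]
    ]
    op = ds.observation_period
    merged = ev.reset_index(drop=True).reset_index(names="_row").merge(
        op[["person_id", "observation_period_start_date", "observation_period_end_date"]],
        on="person_id",
        how="left",
    )
    inside = (
        (merged["event_date"] >= merged["observation_period_start_date"])
        & (merged["event_date"] <= merged["observation_period_end_date"])
    ).fillna(False)
    keep_rows = merged.loc[inside, "_row"].unique()
    ev = ev.iloc[np.sort(keep_rows)]
    return ev.sort_values(["person_id", "event_date", "concept_id"], kind="stable").reset_index(drop=True)


def _person_periods(ds: Dataset) -> dict:
    """person_id -> (starts, ends) sorted ndarray pair."""
    out = {}
    op = ds.observation_period.sort_values("observation_period_start_date")
    for pid, grp in op.groupby("person_id", sort=False):
        out[pid] = (
            grp["observation_period_start_date"].to_numpy(),
            grp["observation_period_end_date"].to_numpy(),
        )
    return out


def _containing_period(starts: np.ndarray, ends: np.ndarray, day: np.datetime64):
    for s, e in zip(starts, ends):
        if s <= day <= e:
            return s, e
    return None


def _entry_for_person(
    days: np.ndarray, starts: np.ndarray, ends: np.ndarray, defn: CohortDefinition
):
    """Return (index_date, period_end) or None for one person.

    ``days`` are the person's distinct qualifying days, ascending.
    """
    low, high = defn.confirmation_window
    need = defn.min_code_count - 1
    candidates = days[:1] if defn.incident else days
    day_unit = np.timedelta64(1, "D")
    for entry in candidates:
        period = _containing_period(starts, ends, entry)
        if period is None:  # cannot happen for in-observation events
            continue
        p_start, p_end = period
        if (entry - p_start) // day_unit < defn.washout_days:
            if defn.incident:
                return None
            continue
        index_date = entry
        if need > 0:
            offsets = (days - entry) // day_unit
            in_window = (offsets >= low) & (offsets <= high) & (days <= p_end)
            conf = days[in_window]
            if len(conf) < need:
                if defn.incident:
                    return None
                continue
            if defn.index_at == "confirmation":
                index_date = conf[need - 1]
        return index_date, p_end
    return None


def build_cohort(ds: Dataset, defn: CohortDefinition) -> Cohort:
    """Execute a phenotype-algorithm definition against a dataset."""
    ev = qualifying_events(ds, defn.concept_set)
    if ev.empty:
        return Cohort(defn.name, pd.DataFrame(_EMPTY_COHORT_COLS))
    periods = _person_periods(ds)
    rows = []
    for pid, grp in ev.groupby("person_id", sort=True):
        days = np.unique(grp["event_date"].to_numpy())
        starts, ends = periods[pid]
        hit = _entry_for_person(days, starts, ends, defn)
        if hit is not None:
            rows.append((pid, hit[0], hit[1]))
    if not rows:
        return Cohort(defn.name, pd.DataFrame(_EMPTY_COHORT_COLS))
    table = pd.DataFrame(rows, columns=["person_id", "cohort_start_date", "cohort_end_date"])
    return Cohort(defn.name, table)


def hs_definitions(
    concept_set: ConceptSet | None = None, index_at: str = "first"
) -> dict[str, CohortDefinition]:
    """The four standard HS phenotype-algorithm definitions."""
    cs = concept_set or hs_concept_set()
    return {
        "incident_1x": CohortDefinition("incident_1x", cs, incident=True, washout_days=365, min_code_count=1),
        "incident_2x": CohortDefinition(
            "incident_2x", cs, incident=True, washout_days=365, min_code_count=2,
            confirmation_window=(31, 365), index_at=index_at,
        ),
        "prevalent_1x": CohortDefinition("prevalent_1x", cs, incident=False, washout_days=0, min_code_count=1),
        "prevalent_2x": CohortDefinition(
            "prevalent_2x", cs, incident=False, washout_days=0, min_code_count=2,
            confirmation_window=(31, 365), index_at=index_at,
        ),
    }


def build_hs_suite(ds: Dataset, concept_set: ConceptSet | None = None) -> dict[str, Cohort]:
    """Build all four standard HS cohorts (all ages, shipped concept set)."""
    return {name: build_cohort(ds, d) for name, d in hs_definitions(concept_set).items()}


def code_count_ladder(
    ds: Dataset, base_defn: CohortDefinition, counts: Iterable[int]
) -> dict[int, Cohort]:
    """Cohorts at increasing required code counts (>=N codes ladder).

    For each N in ``counts`` (ascending, each >= 2) the base definition is
    rebuilt with ``min_code_count=N``; all other settings are untouched.
    Cohorts are nested: cohort(N+1) is a subset of cohort(N).
    """
    counts = list(counts)
    if any(n < 2 for n in counts):
        raise ValueError("ladder counts must each be >= 2")
    if counts != sorted(counts):
        raise ValueError("ladder counts must be ascending")
    out = {}
    for n in counts:
        defn = replace(base_defn, name=f"{base_defn.name}_ge{n}", min_code_count=n)
        out[n] = build_cohort(ds, defn)
    return out
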