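"""Cohort characterization and comparison.

Covers the standard cohort-diagnostics analyses: incidence rates per
100,000 person-years stratified by calendar year, 10-year age band and sex;
windowed binary-covariate characterization; pairwise cohort comparison with
standardized differences of proportions; cohort overlap; and the breakdown
of the diagnosis codes that let subjects into a cohort.

Standardized difference of two proportions
------------------------------------------
For proportions p1, p2 the *unpooled* form is

    d = (p1 - p2) / sqrt(p1(1-p1) + p2(1-p2))

and the *pooled* form divides by sqrt((p1(1-p1) + p2(1-p2)) / 2). The
unpooled form is the default here: the standardized differences printed by
the multi-database HS comparisons (0.66 for HS-code proportions 0.50 vs
0.11; 0.3 for clindamycin proportions 0.32 vs 0.14) are reproduced by the
unpooled form from those proportions, and not by the pooled form. |d| > 0.1
(strict) conventionally flags imbalance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohorts import Cohort, qualifying_events
from .data_model import ConceptSet, Dataset

__all__ = [
    "OverlapResult",
    "smd_binary",
    "incidence_rates",
    "characterize",
    "compare_cohorts",
    "cohort_overlap",
    "index_code_breakdown",
    "AGE_BANDS",
]

DAY = np.timedelta64(1, "D")
DAYS_PER_YEAR = 365.25
IMBALANCE_THRESHOLD = 0.1

#: 10-year age bands, final band open-ended.
AGE_BANDS = tuple(f"{lo}-{lo + 9}" for lo in range(0, 80, 10)) + ("80+",)


def age_band(age: int) -> str:
    if age >= 80:
        return "80+"
    lo = max(int(age) // 10 * 10, 0)
    return f"{lo}-{lo + 9}"


def smd_binary(p1: float, p2: float, variant: str = "unpooled") -> float:
    """Standardized difference between two binary-covariate proportions.

    Returns 0 for the degenerate equal-variance-free cases p1 == p2 in
    {0, 1}; a signed infinity if the proportions differ but both variances
    vanish (p1, p2 opposite corners).
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
    if variant not in ("pooled", "unpooled"):
        raise ValueError("variant must be 'pooled' or 'unpooled'")
    var = p1 * (1 - p1) + p2 * (1 - p2)
    if variant == "pooled":
        var /= 2.0
    if var == 0.0:
        return 0.0 if p1 == p2 else math.copysign(math.inf, p1 - p2)
    return (p1 - p2) / math.sqrt(var)


@dataclass(frozen=True)
class OverlapResult:
    """Set overlap between two cohorts' person sets."""

    only_a: int
    both: int
    only_b: int

    @property
    def size_a(self) -> int:
        return self.only_a + self.both

    @property
    def size_b(self) -> int:
        return self.only_b + self.both


def cohort_overlap(a: Cohort, b: Cohort) -> OverlapResult:
    """Persons only in a, in both, and only in b."""
    sa, sb = a.person_ids, b.person_ids
    both = len(sa & sb)
    return OverlapResult(only_a=len(sa) - both, both=both, only_b=len(sb) - both)


# ---------------------------------------------------------------------------
# incidence


def _eligible_intervals(
    ds: Dataset, index_dates: pd.Series, washout_days: int, window: tuple
) -> pd.DataFrame:
    """Per (person, period): at-risk interval [from, to] clipped to window.

    Eligible time starts after the first ``washout_days`` of each
    observation period (a person cannot index during washout, so that time
    is not at risk), and is censored at the person's index date.
    """
    w_lo, w_hi = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    op = ds.observation_period
    frame = pd.DataFrame(
        {
            "person_id": op["person_id"],
            "from": op["observation_period_start_date"] + pd.Timedelta(days=washout_days),
            "to": op["observation_period_end_date"],
        }
    )
    frame["from"] = frame["from"].clip(lower=w_lo)
    frame["to"] = frame["to"].clip(upper=w_hi)
    idx = frame["person_id"].map(index_dates)
    frame["to"] = frame["to"].where(idx.isna(), np.minimum(frame["to"], idx))
    frame = frame[frame["from"] <= frame["to"]]
    return frame.reset_index(drop=True)


def incidence_rates(
    cohort: Cohort,
    ds: Dataset,
    strata: tuple[str, ...] = ("overall", "year", "age_group", "sex"),
    window: tuple = ("2015-01-01", "2020-12-31"),
    washout_days: int = 365,
) -> pd.DataFrame:
    """Incidence of cohort entry per 100,000 eligible person-years.

    The denominator is the at-risk time of *all* persons in the dataset
    (observation time after the first ``washout_days`` of each period,
    clipped to ``window``, censored at index); the numerator counts index
    dates in the window. Age is index/calendar year minus year of birth.

    Returns a long table (stratum_type, stratum, events, person_years,
    rate_per_100k); rate is NaN where person-time is zero.
    """
    index_dates = cohort.index_dates()
    intervals = _eligible_intervals(ds, index_dates, washout_days, window)
    person_info = ds.person.set_index("person_id")

    # split person-time by calendar year so year and age strata are exact
    pieces = []
    w_lo, w_hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    for year in range(w_lo.year, w_hi.year + 1):
        y_lo, y_hi = pd.Timestamp(year, 1, 1), pd.Timestamp(year, 12, 31)
        lo = intervals["from"].clip(lower=y_lo)
        hi = intervals["to"].clip(upper=y_hi)
        days = (hi - lo).dt.days + 1
        keep = days > 0
        if keep.any():
            pieces.append(
                pd.DataFrame(
                    {"person_id": intervals.loc[keep, "person_id"], "year": year, "days": days[keep]}
                )
            )
    pt = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame(columns=["person_id", "year", "days"])
    pt["sex"] = pt["person_id"].map(person_info["sex"])
    pt["age"] = pt["year"] - pt["person_id"].map(person_info["year_of_birth"])
    pt["age_group"] = pt["age"].clip(lower=0).map(age_band)
    pt["py"] = pt["days"] / DAYS_PER_YEAR

    events = cohort.table[
        (cohort.table["cohort_start_date"] >= w_lo) & (cohort.table["cohort_start_date"] <= w_hi)
    ].copy()
    events["year"] = events["cohort_start_date"].dt.year
    events["sex"] = events["person_id"].map(person_info["sex"])
    events["age"] = events["year"] - events["person_id"].map(person_info["year_of_birth"])
    events["age_group"] = events["age"].clip(lower=0).map(age_band)

    out = []
    for stratum_type in strata:
        if stratum_type == "overall":
            groups = [("all", pt["py"].sum(), len(events))]
        else:
            key = stratum_type if stratum_type != "age_group" else "age_group"
            py_by = pt.groupby(key)["py"].sum()
            ev_by = events.groupby(key).size()
            labels = sorted(set(py_by.index) | set(ev_by.index), key=str)
            groups = [(lab, float(py_by.get(lab, 0.0)), int(ev_by.get(lab, 0))) for lab in labels]
        for label, py, n_ev in groups:
            rate = (n_ev / py) * 100_000 if py > 0 else math.nan
            out.append(
                {
                    "stratum_type": stratum_type,
                    "stratum": str(label),
                    "events": n_ev,
                    "person_years": py,
                    "rate_per_100k": rate,
                }
            )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# characterization


def characterize(cohort: Cohort, ds: Dataset, window: tuple[int, int] = (31, 365)) -> pd.DataFrame:
    """Binary any-occurrence covariate proportions in a window around index.

    For every condition and drug concept: the fraction of cohort persons
    with at least one event dated in [index+low, index+high] (inclusive;
    negative offsets reach before index). Duplicated events do not change
    proportions. Empty cohort -> empty table.
    """
    low, high = window
    if low > high:
        raise ValueError("window low must be <= high")
    cols = ["domain", "concept_id", "n_persons", "proportion"]
    if len(cohort) == 0:
        return pd.DataFrame(columns=cols)
    idx = cohort.table[["person_id", "cohort_start_date"]]
    ev = ds.events(("condition", "drug")).merge(idx, on="person_id", how="inner")
    delta = (ev["event_date"] - ev["cohort_start_date"]).dt.days
    ev = ev[(delta >= low) & (delta <= high)]
    hits = ev.drop_duplicates(["person_id", "domain", "concept_id"])
    counts = hits.groupby(["domain", "concept_id"]).size().reset_index(name="n_persons")
    counts["proportion"] = counts["n_persons"] / len(cohort)
    return counts[cols].sort_values(["domain", "concept_id"]).reset_index(drop=True)


def compare_cohorts(
    a: Cohort,
    b: Cohort,
    ds: Dataset,
    window: tuple[int, int] = (31, 365),
    variant: str = "unpooled",
) -> pd.DataFrame:
    """Join two characterizations and compute per-covariate standardized
    differences; |smd| > 0.1 (strict) flags imbalance.

    Concepts absent from one cohort's characterization enter with
    proportion 0. Symmetric up to the sign of smd.
    """
    ca = characterize(a, ds, window).rename(columns={"proportion": "p1"})[["domain", "concept_id", "p1"]]
    cb = characterize(b, ds, window).rename(columns={"proportion": "p2"})[["domain", "concept_id", "p2"]]
    merged = ca.merge(cb, on=["domain", "concept_id"], how="outer")
    merged[["p1", "p2"]] = merged[["p1", "p2"]].astype(float).fillna(0.0)
    merged["smd"] = [smd_binary(r.p1, r.p2, variant) for r in merged.itertuples()]
    merged["imbalanced"] = merged["smd"].abs() > IMBALANCE_THRESHOLD
    return merged.sort_values(["domain", "concept_id"]).reset_index(drop=True)


def index_code_breakdown(cohort: Cohort, ds: Dataset, cs: ConceptSet) -> pd.DataFrame:
    """Counts of the diagnosis concepts that let subjects into the cohort.

    For each member, every distinct qualifying concept dated exactly on the
    index date counts once; members entering on a multi-concept day are
    flagged, so counts can sum to more than the cohort size.
    """
    cols = ["concept_id", "n_entries", "n_tied"]
    if len(cohort) == 0:
        return pd.DataFrame(columns=cols)
    ev = qualifying_events(ds, cs)
    merged = ev.merge(cohort.table[["person_id", "cohort_start_date"]], on="person_id", how="inner")
    at_index = merged[merged["event_date"] == merged["cohort_start_date"]]
    at_index = at_index.drop_duplicates(["person_id", "concept_id"])
    missing = cohort.person_ids - set(at_index["person_id"])
    if missing:
        raise ValueError(
            f"{len(missing)} cohort member(s) have no qualifying code on their index date, "
            f"e.g. {sorted(missing)[:3]}"
        )
    per_person = at_index.groupby("person_id").size()
    tied_people = set(per_person[per_person > 1].index)
    counts = at_index.groupby("concept_id").size().reset_index(name="n_entries")
    counts["n_tied"] = [
        int(at_index[(at_index["concept_id"] == c)]["person_id"].isin(tied_people).sum())
        for c in counts["concept_id"]
    ]
    return counts[cols].sort_values("n_entries", ascending=False).reset_index(drop=True)
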