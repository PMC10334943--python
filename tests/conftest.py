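"""Shared fixtures: hand-built toy datasets and cached simulations."""

from __future__ import annotations

import pandas as pd
import pytest

from phenoforge import Dataset, simulate_population, validation_like


def make_dataset(people: dict) -> Dataset:
    """Build a Dataset from a compact per-person spec.

    ``people`` maps person_id -> dict with keys:
      periods: list of (start, end) date strings (required)
      hs: list of HS-code dates or (concept_id, date) pairs
      conditions / drugs: list of (concept_id, date) pairs
      visits: list of date strings
      sex (default female), yob (default 1980)
    """
    persons, periods, visits, conds, drugs = [], [], [], [], []
    for pid, spec in people.items():
        persons.append(
            {"person_id": pid, "sex": spec.get("sex", "female"), "year_of_birth": spec.get("yob", 1980)}
        )
        for s, e in spec["periods"]:
            periods.append(
                {
                    "person_id": pid,
                    "observation_period_start_date": pd.Timestamp(s),
                    "observation_period_end_date": pd.Timestamp(e),
                }
            )
        for item in spec.get("hs", []):
            concept, date = item if isinstance(item, tuple) else (4241223, item)
            conds.append(
                {"person_id": pid, "condition_concept_id": concept, "condition_start_date": pd.Timestamp(date)}
            )
        for concept, date in spec.get("conditions", []):
            conds.append(
                {"person_id": pid, "condition_concept_id": concept, "condition_start_date": pd.Timestamp(date)}
            )
        for concept, date in spec.get("drugs", []):
            drugs.append(
                {"person_id": pid, "drug_concept_id": concept, "drug_exposure_start_date": pd.Timestamp(date)}
            )
        for date in spec.get("visits", []):
            visits.append(
                {"person_id": pid, "visit_start_date": pd.Timestamp(date), "visit_type": "outpatient"}
            )
    return Dataset(
        person=pd.DataFrame(persons),
        observation_period=pd.DataFrame(periods),
        visit_occurrence=pd.DataFrame(visits) if visits else pd.DataFrame(),
        condition_occurrence=pd.DataFrame(conds) if conds else pd.DataFrame(),
        drug_exposure=pd.DataFrame(drugs) if drugs else pd.DataFrame(),
    )


@pytest.fixture
def abc_dataset() -> Dataset:
    """Three textbook persons covering the incident/prevalent entry cases.

    A: long enrollment, two codes 61 days apart (enters everything).
    B: code 60 days into enrollment, no second code (prevalent-1x only).
    C: long enrollment, second code 14 days after the first (fails the
       31-365 day confirmation window).
    """
    return make_dataset(
        {
            "A": {"periods": [("2014-01-01", "2020-12-31")], "hs": ["2016-03-01", "2016-05-01"]},
            "B": {"periods": [("2016-01-01", "2017-12-31")], "hs": ["2016-03-01"]},
            "C": {"periods": [("2010-01-01", "2020-12-31")], "hs": ["2012-01-01", "2012-01-15"]},
        }
    )


@pytest.fixture(scope="session")
def sim_small():
    """Mid-size enriched simulation shared by structural-invariant tests."""
    params = validation_like(n_persons=8_000, seed=42)
    ds, truth = simulate_population(params)
    return params, ds, truth
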