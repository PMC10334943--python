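import datetime as dt
import random

import numpy as np
import pandas as pd
import pytest

from phenoforge import (
    CohortDefinition,
    build_cohort,
    build_hs_suite,
    code_count_ladder,
    hs_concept_set,
    hs_definitions,
    qualifying_events,
)

from bruteforce import brute_force_entry
from conftest import make_dataset

HS = hs_concept_set()


def index_of(cohort, pid):
    return cohort.table.set_index("person_id")["cohort_start_date"].get(pid)


# ---------------------------------------------------------------------------
# qualifying events


def test_qualifying_events_sorted_and_filtered():
    ds = make_dataset(
        {
            1: {
                "periods": [("2016-01-01", "2017-12-31")],
                "hs": ["2016-05-01", "2016-03-01", "2015-06-01"],  # last is pre-enrollment
                "conditions": [(316866, "2016-04-01")],  # non-HS concept
            }
        }
    )
    ev = qualifying_events(ds, HS)
    assert list(ev["event_date"]) == [pd.Timestamp("2016-03-01"), pd.Timestamp("2016-05-01")]


def test_qualifying_events_empty_without_hs_codes():
    ds = make_dataset({1: {"periods": [("2016-01-01", "2016-12-31")], "conditions": [(316866, "2016-04-01")]}})
    assert qualifying_events(ds, HS).empty


# ---------------------------------------------------------------------------
# the four standard algorithms on the textbook persons


def test_standard_suite_membership(abc_dataset):
    suite = build_hs_suite(abc_dataset)
    assert suite["incident_1x"].person_ids == {"A", "C"}
    assert suite["incident_2x"].person_ids == {"A"}
    assert suite["prevalent_1x"].person_ids == {"A", "B", "C"}
    assert suite["prevalent_2x"].person_ids == {"A"}
    # index at the first qualifying code
    assert index_of(suite["incident_1x"], "A") == pd.Timestamp("2016-03-01")
    assert index_of(suite["incident_2x"], "A") == pd.Timestamp("2016-03-01")
    assert index_of(suite["prevalent_1x"], "B") == pd.Timestamp("2016-03-01")
    # exit at end of the enclosing observation period
    assert suite["incident_1x"].table.set_index("person_id")["cohort_end_date"]["A"] == pd.Timestamp("2020-12-31")


def test_empty_dataset_gives_four_empty_cohorts():
    ds = make_dataset({1: {"periods": [("2016-01-01", "2016-12-31")]}})
    assert all(len(c) == 0 for c in build_hs_suite(ds).values())


def test_index_at_confirmation_moves_index_not_membership(abc_dataset):
    first = build_cohort(abc_dataset, hs_definitions()["incident_2x"])
    second = build_cohort(abc_dataset, hs_definitions(index_at="confirmation")["incident_2x"])
    assert first.person_ids == second.person_ids == {"A"}
    assert index_of(second, "A") == pd.Timestamp("2016-05-01")


# ---------------------------------------------------------------------------
# boundary semantics


@pytest.mark.parametrize(
    "gap_days,expected",
    [(30, False), (31, True), (365, True), (366, False)],
)
def test_confirmation_window_inclusive_endpoints(gap_days, expected):
    second = dt.date(2016, 1, 1) + dt.timedelta(days=gap_days)
    ds = make_dataset(
        {1: {"periods": [("2014-01-01", "2020-12-31")], "hs": ["2016-01-01", str(second)]}}
    )
    cohort = build_cohort(ds, hs_definitions()["prevalent_2x"])
    assert (1 in cohort) == expected


@pytest.mark.parametrize("prior_days,expected", [(364, False), (365, True)])
def test_washout_boundary(prior_days, expected):
    code = dt.date(2015, 1, 1) + dt.timedelta(days=prior_days)
    ds = make_dataset({1: {"periods": [("2015-01-01", "2020-12-31")], "hs": [str(code)]}})
    cohort = build_cohort(ds, hs_definitions()["incident_1x"])
    assert (1 in cohort) == expected


def test_observation_gap_breaks_washout_continuity():
    # 5 years of history split into two periods; code 100 days into period 2
    ds = make_dataset(
        {1: {"periods": [("2010-01-01", "2014-12-31"), ("2016-01-01", "2019-12-31")], "hs": ["2016-04-10"]}}
    )
    assert 1 not in build_cohort(ds, hs_definitions()["incident_1x"])


def test_confirmation_must_share_observation_period():
    ds = make_dataset(
        {
            1: {
                "periods": [("2015-01-01", "2016-03-01"), ("2016-03-02", "2018-12-31")],
                "hs": ["2016-01-01", "2016-06-01"],  # 152 days apart but periods differ
            }
        }
    )
    assert 1 not in build_cohort(ds, hs_definitions()["prevalent_2x"])


def test_incident_person_excluded_entirely_when_first_code_fails():
    # first-ever code inside washout; a later code would pass, but the
    # cohort must stay incident
    ds = make_dataset(
        {1: {"periods": [("2015-01-01", "2020-12-31")], "hs": ["2015-03-01", "2017-03-01", "2017-05-01"]}}
    )
    assert 1 not in build_cohort(ds, hs_definitions()["incident_1x"])
    # prevalent logic defers to the first passing code instead
    prev = build_cohort(ds, hs_definitions()["prevalent_2x"])
    assert index_of(prev, 1) == pd.Timestamp("2017-03-01")


def test_same_day_duplicate_codes_do_not_confirm():
    ds = make_dataset(
        {1: {"periods": [("2014-01-01", "2020-12-31")], "hs": [(4241223, "2016-01-01"), (434119, "2016-01-01")]}}
    )
    assert 1 not in build_cohort(ds, hs_definitions()["prevalent_2x"])
    assert len(build_cohort(ds, hs_definitions()["prevalent_1x"])) == 1


# ---------------------------------------------------------------------------
# ladder


def test_code_count_ladder_counts(abc_dataset):
    base = hs_definitions()["prevalent_2x"]
    ladder = code_count_ladder(abc_dataset, base, [2, 3])
    assert ladder[2].person_ids == {"A"}
    assert ladder[3].person_ids == set()


def test_ladder_person_with_five_codes_in_window():
    dates = ["2016-01-01"] + [str(dt.date(2016, 1, 1) + dt.timedelta(days=40 + 20 * k)) for k in range(4)]
    ds = make_dataset({1: {"periods": [("2014-01-01", "2020-12-31")], "hs": dates}})
    ladder = code_count_ladder(ds, hs_definitions()["prevalent_2x"], [2, 3, 4, 5])
    assert all(1 in ladder[n] for n in (2, 3, 4, 5))


def test_ladder_rejects_bad_counts(abc_dataset):
    base = hs_definitions()["prevalent_2x"]
    with pytest.raises(ValueError):
        code_count_ladder(abc_dataset, base, [1, 2])
    with pytest.raises(ValueError):
        code_count_ladder(abc_dataset, base, [3, 2])


def test_definition_invariants_enforced():
    with pytest.raises(ValueError):
        CohortDefinition("bad", HS, min_code_count=0)
    with pytest.raises(ValueError):
        CohortDefinition("bad", HS, confirmation_window=(0, 365))
    with pytest.raises(ValueError):
        CohortDefinition("bad", HS, confirmation_window=(31, 30))
    with pytest.raises(ValueError):
        CohortDefinition("bad", HS, washout_days=-1)


# ---------------------------------------------------------------------------
# structural properties


def test_nesting_and_subset_structure(sim_small):
    _, ds, _ = sim_small
    suite = build_hs_suite(ds)
    assert suite["incident_2x"].person_ids <= suite["incident_1x"].person_ids
    assert suite["incident_1x"].person_ids <= suite["prevalent_1x"].person_ids
    assert suite["incident_2x"].person_ids <= suite["prevalent_2x"].person_ids
    assert suite["prevalent_2x"].person_ids <= suite["prevalent_1x"].person_ids


def test_cohorts_antitone_in_washout_and_code_count(sim_small):
    _, ds, _ = sim_small
    base = hs_definitions()["prevalent_2x"]
    from dataclasses import replace

    members = [
        build_cohort(ds, replace(base, min_code_count=n)).person_ids for n in (1, 2, 3)
    ]
    assert members[2] <= members[1] <= members[0]
    washouts = [
        build_cohort(ds, replace(base, washout_days=w)).person_ids for w in (0, 180, 365)
    ]
    assert washouts[2] <= washouts[1] <= washouts[0]


def test_date_shift_invariance(abc_dataset):
    shift = pd.Timedelta(days=123)
    shifted = make_dataset({})
    shifted.person = abc_dataset.person.copy()
    for name in ("observation_period", "visit_occurrence", "condition_occurrence", "drug_exposure"):
        df = getattr(abc_dataset, name).copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col] + shift
        setattr(shifted, name, df)
    for name, defn in hs_definitions().items():
        a = build_cohort(abc_dataset, defn)
        b = build_cohort(shifted, defn)
        assert a.person_ids == b.person_ids
        merged = a.table.merge(b.table, on="person_id", suffixes=("_a", "_b"))
        assert ((merged["cohort_start_date_b"] - merged["cohort_start_date_a"]) == shift).all()


# ---------------------------------------------------------------------------
# brute-force oracle equivalence (randomized persons and definitions)


def _random_person(rnd: random.Random):
    base = dt.date(2010, 1, 1)
    periods = []
    cursor = base + dt.timedelta(days=rnd.randrange(0, 400))
    for _ in range(rnd.choice([1, 1, 2])):
        length = rnd.randrange(50, 1500)
        periods.append((cursor, cursor + dt.timedelta(days=length)))
        cursor += dt.timedelta(days=length + rnd.randrange(1, 300))
    n_codes = rnd.randrange(0, 7)
    span = (periods[-1][1] - periods[0][0]).days
    codes = [
        periods[0][0] + dt.timedelta(days=rnd.randrange(-100, span + 100)) for _ in range(n_codes)
    ]
    if codes and rnd.random() < 0.3:
        codes.append(codes[0])  # same-day duplicate
    return periods, codes


def _random_definition(rnd: random.Random):
    low = rnd.choice([1, 14, 31])
    return dict(
        incident=rnd.random() < 0.5,
        washout_days=rnd.choice([0, 90, 365]),
        min_code_count=rnd.choice([1, 2, 2, 3]),
        window=(low, low + rnd.choice([60, 334])),
        index_at=rnd.choice(["first", "confirmation"]),
    )


def test_engine_matches_brute_force_on_random_persons():
    """Literal per-person enumeration agrees with the vectorised engine on
    1,200 randomized persons across randomized definitions."""
    rnd = random.Random(20240917)
    for batch in range(12):
        spec = _random_definition(rnd)
        people, expected = {}, {}
        for pid in range(100):
            periods, codes = _random_person(rnd)
            people[pid] = {
                "periods": [(str(s), str(e)) for s, e in periods],
                "hs": [str(c) for c in codes],
            }
            expected[pid] = brute_force_entry(
                codes,
                periods,
                incident=spec["incident"],
                washout_days=spec["washout_days"],
                min_code_count=spec["min_code_count"],
                window=spec["window"],
                index_at=spec["index_at"],
            )
        ds = make_dataset(people)
        defn = CohortDefinition(
            name=f"rand{batch}",
            concept_set=HS,
            incident=spec["incident"],
            washout_days=spec["washout_days"],
            min_code_count=spec["min_code_count"],
            confirmation_window=spec["window"],
            index_at=spec["index_at"],
        )
        got = build_cohort(ds, defn).table.set_index("person_id")["cohort_start_date"].to_dict()
        want = {pid: pd.Timestamp(d) for pid, d in expected.items() if d is not None}
        assert got == want, f"mismatch in batch {batch} ({spec})"
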