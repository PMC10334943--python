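"""Synthetic OMOP-style claims data with known ground-truth disease status.

The generator emulates the data-generating reality behind administrative
claims and EHR databases: per-person enrollment spans, a memoryless visit
process, a latent true-disease onset process (a mix of onsets predating
enrollment — prevalent cases — and a uniform onset hazard over observed
time — incident cases), imperfect per-visit diagnosis coding (false
negatives via ``coding_sensitivity`` < 1, false positives via
``coding_fp_rate``), and disease-correlated comorbidity and drug codes.

Ground truth (who truly has the disease, and since when) is returned
alongside the dataset, so every downstream stage — cohort logic,
incidence estimation, probabilistic validation — has an exact oracle.

Two presets are shipped:

* :func:`ccae_like` — a large US commercial-claims-like database:
  ~4 visits/person-year, true HS incidence 12 per 100,000 person-years,
  modest coding sensitivity (0.35), very rare false-positive coding.
  Realistic rarity, hence very few cases at test-scale n.
* :func:`validation_like` — the same structure with enriched prevalence,
  incidence and false-positive coding plus strong treatment/comorbidity
  signal, sized so that algorithm performance metrics are estimable at
  n of a few tens of thousands and land in the ranges reported by
  multi-database validation studies of HS phenotype algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    HIDRADENITIS_CONCEPT,
    HS_SUPPURATIVA_CONCEPT,
    Dataset,
    _write_iso,
)
from .metrics import PerformanceMetrics

__all__ = [
    "Comorbidity",
    "SimulationParams",
    "simulate_population",
    "true_performance",
    "ccae_like",
    "validation_like",
    "write_truth",
    "read_truth",
]

DAY = np.timedelta64(1, "D")


@dataclass(frozen=True)
class Comorbidity:
    """A disease-correlated concept emitted per visit.

    ``per_visit_prob`` is the baseline emission probability at any visit;
    post-onset visits of true cases use ``per_visit_prob * case_rate_ratio``
    (capped at 1). Concepts with ratio 1 are background noise.
    """

    concept_id: int
    domain: str  # "condition" | "drug"
    name: str
    per_visit_prob: float
    case_rate_ratio: float = 1.0


# Concept ids are opaque integers; these mimic OMOP standard-concept ids for
# recognisability but carry no vocabulary semantics here.
DEFAULT_COMORBIDITIES: tuple[Comorbidity, ...] = (
    Comorbidity(1754994, "drug", "clindamycin-like", 0.004, 25.0),
    Comorbidity(1836430, "drug", "doxycycline-like", 0.006, 15.0),
    Comorbidity(4148828, "condition", "skin-abscess-like", 0.005, 22.0),
    Comorbidity(201826, "condition", "type-2-diabetes-like", 0.015, 2.5),
    Comorbidity(433736, "condition", "obesity-like", 0.010, 2.5),
    Comorbidity(316866, "condition", "hypertension-like", 0.030, 1.3),
    Comorbidity(436665, "condition", "depression-like", 0.020, 1.8),
    Comorbidity(255573, "condition", "copd-like", 0.010, 1.0),
    Comorbidity(4329847, "condition", "mi-like", 0.003, 1.0),
    Comorbidity(140168, "condition", "acne-like", 0.008, 4.0),
    Comorbidity(80180, "condition", "osteoarthritis-like", 0.015, 1.0),
    Comorbidity(437663, "condition", "fever-like", 0.020, 1.0),
    Comorbidity(1125315, "drug", "acetaminophen-like", 0.040, 1.0),
    Comorbidity(1139042, "drug", "amoxicillin-like", 0.025, 1.0),
    Comorbidity(923645, "drug", "omeprazole-like", 0.020, 1.0),
    Comorbidity(1308216, "drug", "lisinopril-like", 0.020, 1.2),
)


# Variant used by the validation preset: the treatment-pattern concepts
# (repeated topical/oral antibiotic courses, recurrent skin abscesses) are
# made highly disease-specific so a diagnostic model fitted on coded data
# can separate cases; background utilisation concepts are unchanged.
VALIDATION_COMORBIDITIES: tuple[Comorbidity, ...] = (
    Comorbidity(1754994, "drug", "clindamycin-like", 0.0008, 375.0),
    Comorbidity(1836430, "drug", "doxycycline-like", 0.0010, 300.0),
    Comorbidity(4148828, "condition", "skin-abscess-like", 0.0008, 375.0),
    Comorbidity(140168, "condition", "acne-like", 0.002, 75.0),
    Comorbidity(201826, "condition", "type-2-diabetes-like", 0.015, 2.5),
    Comorbidity(433736, "condition", "obesity-like", 0.010, 2.5),
    Comorbidity(316866, "condition", "hypertension-like", 0.030, 1.3),
    Comorbidity(436665, "condition", "depression-like", 0.020, 1.8),
    Comorbidity(255573, "condition", "copd-like", 0.010, 1.0),
    Comorbidity(4329847, "condition", "mi-like", 0.003, 1.0),
    Comorbidity(80180, "condition", "osteoarthritis-like", 0.015, 1.0),
    Comorbidity(437663, "condition", "fever-like", 0.020, 1.0),
    Comorbidity(1125315, "drug", "acetaminophen-like", 0.040, 1.0),
    Comorbidity(1139042, "drug", "amoxicillin-like", 0.025, 1.0),
    Comorbidity(923645, "drug", "omeprazole-like", 0.020, 1.0),
    Comorbidity(1308216, "drug", "lisinopril-like", 0.020, 1.2),
)


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the generator. Probabilities in [0,1]; rates >= 0."""

    n_persons: int = 10_000
    study_start: str = "2015-01-01"
    study_end: str = "2020-12-31"
    enrollment_mean_years: float = 2.5
    visit_rate: float = 4.0  # expected visits per person-year
    case_visit_multiplier: float = 2.0  # post-onset visit-rate multiplier
    annual_incidence: float = 12.0  # true onsets per 100,000 person-years
    baseline_prevalence: float = 5e-4  # fraction with onset before enrollment
    coding_sensitivity: float = 0.35  # P(HS code | post-onset visit of a case)
    coding_fp_rate: float = 2e-5  # P(HS code | visit of a non-case)
    female_fraction: float = 0.51
    birth_year_range: tuple[int, int] = (1940, 2005)
    hs_code_mix: float = 0.45  # P(coded event uses the L73.2-mapped concept)
    comorbidity_spec: tuple[Comorbidity, ...] = DEFAULT_COMORBIDITIES
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "baseline_prevalence": self.baseline_prevalence,
            "coding_sensitivity": self.coding_sensitivity,
            "coding_fp_rate": self.coding_fp_rate,
            "female_fraction": self.female_fraction,
            "hs_code_mix": self.hs_code_mix,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        for name in ("visit_rate", "annual_incidence", "enrollment_mean_years", "case_visit_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for cm in self.comorbidity_spec:
            if not 0.0 <= cm.per_visit_prob <= 1.0 or cm.case_rate_ratio < 0:
                raise ValueError(f"invalid comorbidity spec for concept {cm.concept_id}")


def ccae_like(n_persons: int = 50_000, seed: int = 0, **overrides) -> SimulationParams:
    """Commercial-claims-like preset (realistic HS rarity)."""
    return replace(SimulationParams(), n_persons=n_persons, seed=seed, **overrides)


def validation_like(n_persons: int = 50_000, seed: int = 0, **overrides) -> SimulationParams:
    """Enriched preset for algorithm-validation experiments.

    At realistic HS incidence (12/100,000 PY) a 50,000-person database holds
    on the order of ten true cases — far too few to estimate PPV or
    sensitivity. This preset raises disease frequency (to an enriched,
    case-control-like mix) and false-positive coding so that cohorts number
    in the hundreds-to-thousands and the four algorithms separate in
    performance, and makes the treatment-pattern concepts highly
    disease-specific so a probabilistic reference model is informable,
    while keeping the coding structure of the claims process intact.
    """
    base = SimulationParams(
        enrollment_mean_years=3.0,
        annual_incidence=600.0,
        baseline_prevalence=0.04,
        case_visit_multiplier=3.0,
        coding_sensitivity=0.35,
        coding_fp_rate=3e-4,
        hs_code_mix=0.6,
        comorbidity_spec=VALIDATION_COMORBIDITIES,
    )
    return replace(base, n_persons=n_persons, seed=seed, **overrides)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """One named random stream per table, all derived from the global seed."""
    names = ("person", "period", "truth", "visit", "coding", "comorbidity")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def simulate_population(params: SimulationParams) -> tuple[Dataset, pd.DataFrame]:
    """Generate a dataset plus its truth table.

    Returns ``(dataset, truth)`` where truth has columns person_id,
    true_case (bool), onset_date (NaT for non-cases). Identical params
    (including seed) give identical output.
    """
    rng = _streams(params.seed)
    n = params.n_persons
    start = np.datetime64(params.study_start)
    end = np.datetime64(params.study_end)
    window_days = int((end - start) // DAY)
    if window_days < 31:
        raise ValueError("study window must span at least 31 days")

    person_id = np.arange(1, n + 1)
    sex = np.where(rng["person"].random(n) < params.female_fraction, "female", "male")
    yob = rng["person"].integers(params.birth_year_range[0], params.birth_year_range[1] + 1, size=n)
    person = pd.DataFrame({"person_id": person_id, "sex": sex, "year_of_birth": yob})

    # one observation period per person, clipped to the study window
    op_start_off = rng["period"].integers(0, max(window_days - 30, 1), size=n)
    duration = np.maximum(rng["period"].exponential(params.enrollment_mean_years * 365.25, size=n), 30.0)
    op_start = start + op_start_off * DAY
    op_end = np.minimum(op_start + duration.astype("int64") * DAY, end)
    obs_days = ((op_end - op_start) // DAY).astype("int64") + 1  # inclusive day count
    obs_years = obs_days / 365.25
    observation_period = pd.DataFrame(
        {
            "person_id": person_id,
            "observation_period_start_date": op_start,
            "observation_period_end_date": op_end,
        }
    )

    # latent truth: prevalent cases (onset before enrollment) + incident onsets
    # under a uniform hazard over observed time
    prevalent = rng["truth"].random(n) < params.baseline_prevalence
    lam = params.annual_incidence / 100_000.0
    p_onset = 1.0 - np.exp(-lam * obs_years)
    incident = (~prevalent) & (rng["truth"].random(n) < p_onset)
    onset = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    onset[prevalent] = (op_start.astype("datetime64[D]")[prevalent]
                        - rng["truth"].integers(1, 5 * 365, size=int(prevalent.sum())) * DAY)
    frac = rng["truth"].random(int(incident.sum()))
    onset[incident] = op_start.astype("datetime64[D]")[incident] + np.floor(
        frac * obs_days[incident]
    ).astype("int64") * DAY
    true_case = prevalent | incident
    truth = pd.DataFrame(
        {
            "person_id": person_id,
            "true_case": true_case,
            "onset_date": pd.to_datetime(onset),
        }
    )

    # visits: pre-onset segment at visit_rate, post-onset at an elevated rate
    onset_clip = np.where(true_case, np.maximum(onset.astype("datetime64[ns]"), op_start), op_end + DAY)
    pre_days = np.where(true_case, (onset_clip - op_start) // DAY, obs_days)
    post_days = obs_days - pre_days
    pre_mu = params.visit_rate * pre_days / 365.25
    post_mu = params.visit_rate * params.case_visit_multiplier * post_days / 365.25
    n_pre = rng["visit"].poisson(pre_mu)
    n_post = rng["visit"].poisson(post_mu)

    def _scatter(counts: np.ndarray, seg_start: np.ndarray, seg_len: np.ndarray):
        owner = np.repeat(np.arange(n), counts)
        offs = np.floor(rng["visit"].random(counts.sum()) * np.repeat(seg_len, counts)).astype("int64")
        return owner, seg_start[owner] + offs * DAY

    pre_owner, pre_dates = _scatter(n_pre, op_start, np.maximum(pre_days, 1))
    post_owner, post_dates = _scatter(n_post, onset_clip.astype("datetime64[ns]"), np.maximum(post_days, 1))
    v_owner = np.concatenate([pre_owner, post_owner])
    v_dates = np.concatenate([pre_dates, post_dates])
    order = np.lexsort((v_dates.astype("int64"), v_owner))
    v_owner, v_dates = v_owner[order], v_dates[order]
    v_type = rng["visit"].choice(
        np.array(["outpatient", "inpatient", "emergency"]), size=len(v_owner), p=[0.85, 0.05, 0.10]
    )
    visit_occurrence = pd.DataFrame(
        {"person_id": person_id[v_owner], "visit_start_date": v_dates, "visit_type": v_type}
    )

    # diagnosis coding at visits
    post_onset_visit = true_case[v_owner] & (v_dates >= onset_clip[v_owner])
    noncase_visit = ~true_case[v_owner]
    u = rng["coding"].random(len(v_owner))
    coded = (post_onset_visit & (u < params.coding_sensitivity)) | (
        noncase_visit & (u < params.coding_fp_rate)
    )
    hs_concept = np.where(
        rng["coding"].random(len(v_owner)) < params.hs_code_mix,
        HS_SUPPURATIVA_CONCEPT,
        HIDRADENITIS_CONCEPT,
    )
    cond_frames = [
        pd.DataFrame(
            {
                "person_id": person_id[v_owner[coded]],
                "condition_concept_id": hs_concept[coded],
                "condition_start_date": v_dates[coded],
            }
        )
    ]

    # comorbidity / drug coding at visits
    drug_frames = []
    for cm in params.comorbidity_spec:
        p = np.where(post_onset_visit, min(cm.per_visit_prob * cm.case_rate_ratio, 1.0), cm.per_visit_prob)
        hit = rng["comorbidity"].random(len(v_owner)) < p
        frame = pd.DataFrame({"person_id": person_id[v_owner[hit]], "event_date": v_dates[hit]})
        if cm.domain == "condition":
            cond_frames.append(
                frame.rename(columns={"event_date": "condition_start_date"}).assign(
                    condition_concept_id=cm.concept_id
                )[["person_id", "condition_concept_id", "condition_start_date"]]
            )
        else:
            drug_frames.append(
                frame.rename(columns={"event_date": "drug_exposure_start_date"}).assign(
                    drug_concept_id=cm.concept_id
                )[["person_id", "drug_concept_id", "drug_exposure_start_date"]]
            )

    condition_occurrence = (
        pd.concat(cond_frames, ignore_index=True)
        .sort_values(["person_id", "condition_start_date", "condition_concept_id"], kind="stable")
        .reset_index(drop=True)
    )
    drug_exposure = (
        pd.concat(drug_frames, ignore_index=True)
        .sort_values(["person_id", "drug_exposure_start_date", "drug_concept_id"], kind="stable")
        .reset_index(drop=True)
        if drug_frames
        else pd.DataFrame(
            {
                "person_id": pd.Series(dtype="int64"),
                "drug_concept_id": pd.Series(dtype="int64"),
                "drug_exposure_start_date": pd.Series(dtype="datetime64[ns]"),
            }
        )
    )

    ds = Dataset(
        person=person,
        observation_period=observation_period,
        visit_occurrence=visit_occurrence,
        condition_occurrence=condition_occurrence,
        drug_exposure=drug_exposure,
    )
    return ds, truth


def true_performance(truth: pd.DataFrame, cohort, eligible) -> PerformanceMetrics:
    """Gold-standard confusion matrix of a cohort against the truth table.

    ``eligible`` is the evaluated person set; every cohort member must be in
    it. Labels are ``true_case``; predictions are cohort membership.
    """
    eligible = set(eligible)
    members = cohort.person_ids
    stray = members - eligible
    if stray:
        raise ValueError(f"{len(stray)} cohort person(s) not in the eligible set, e.g. {sorted(stray)[:3]}")
    t = truth[truth["person_id"].isin(eligible)]
    label = t["true_case"].to_numpy(dtype=bool)
    pred = t["person_id"].isin(members).to_numpy()
    tp = int((label & pred).sum())
    fp = int((~label & pred).sum())
    fn = int((label & ~pred).sum())
    tn = int((~label & ~pred).sum())
    return PerformanceMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


def write_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    _write_iso(truth, path)
    return path


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["onset_date"] = pd.to_datetime(df["onset_date"], format="ISO8601")
    df["true_case"] = df["true_case"].astype(bool)
    return df
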