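"""Probabilistic validation of phenotype algorithms without chart review.

The approach estimates sensitivity, specificity, PPV and NPV of a cohort
definition by replacing chart-review labels with a probabilistic reference
standard:

1. An extremely specific "xSpec" cohort (persons with many distinct-day
   diagnosis codes, default >= 5) supplies noisy-positive training labels;
   persons with zero qualifying codes supply noisy negatives.
2. A regularized logistic diagnostic model is fitted on binary
   concept-occurrence features in a window around each person's anchor
   date. The phenotype's own diagnosis concepts are excluded from the
   feature space so the evaluated codes cannot leak into the reference.
3. The model scores a random evaluation sample, giving each person a
   probability p of truly having the disease.
4. The expected confusion matrix against the cohort's membership vector is
   tp = sum(p) over members, fp = sum(1-p) over members, fn = sum(p) over
   non-members, tn = sum(1-p) over non-members; metrics follow, with
   percentile-bootstrap 95% intervals over the evaluation sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.linear_model import LogisticRegressionCV

from .cohorts import Cohort, CohortDefinition, build_cohort, qualifying_events
from .data_model import ConceptSet, Dataset
from .metrics import METRIC_NAMES, PerformanceMetrics

__all__ = [
    "EvalConfig",
    "EvaluationResult",
    "build_xspec_cohort",
    "build_negative_sample",
    "extract_features",
    "fit_diagnostic_model",
    "predict_disease_probability",
    "probabilistic_confusion",
    "evaluate_algorithm",
]

DAY = np.timedelta64(1, "D")


def build_xspec_cohort(ds: Dataset, cs: ConceptSet, min_codes: int = 5) -> Cohort:
    """Noisy-positive training cohort: >= ``min_codes`` codes on distinct days.

    Index at the first qualifying code. With ``min_codes=1`` this collapses
    to prevalent one-code membership.
    """
    if min_codes < 1:
        raise ValueError("min_codes must be >= 1")
    ev = qualifying_events(ds, cs)
    if ev.empty:
        return Cohort("xspec", pd.DataFrame({
            "person_id": pd.Series(dtype="object"),
            "cohort_start_date": pd.Series(dtype="datetime64[ns]"),
            "cohort_end_date": pd.Series(dtype="datetime64[ns]"),
        }))
    days = ev.drop_duplicates(["person_id", "event_date"])
    g = days.groupby("person_id")["event_date"]
    agg = g.agg(["count", "min"]).reset_index()
    hit = agg[agg["count"] >= min_codes]
    op = ds.observation_period
    end = op.groupby("person_id")["observation_period_end_date"].max()
    table = pd.DataFrame(
        {
            "person_id": hit["person_id"],
            "cohort_start_date": hit["min"],
            "cohort_end_date": hit["person_id"].map(end),
        }
    ).reset_index(drop=True)
    return Cohort("xspec", table)


def build_negative_sample(
    ds: Dataset, cs: ConceptSet, n: int, rng: np.random.Generator | int, tail_days: int = 0
) -> pd.DataFrame:
    """Uniform sample of code-free persons with random in-observation anchors.

    Anchors are drawn so that at least ``tail_days`` of observation follow
    them (persons who cannot satisfy that are not sampled). Returns columns
    person_id, anchor_date; reproducible given the rng/seed.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    coded = set(qualifying_events(ds, cs)["person_id"])
    spans = _longest_period(ds)
    long_enough = set(spans.index[(spans["_len"] // DAY) >= tail_days])
    pool = ds.person.loc[
        ~ds.person["person_id"].isin(coded) & ds.person["person_id"].isin(long_enough), "person_id"
    ].to_numpy()
    if n > len(pool):
        raise ValueError(f"requested {n} negatives but only {len(pool)} eligible code-free persons exist")
    chosen = rng.choice(pool, size=n, replace=False) if n else pool[:0]
    anchors = _random_anchor_dates(ds, chosen, rng, tail_days)
    return pd.DataFrame({"person_id": chosen, "anchor_date": anchors})


def _longest_period(ds: Dataset) -> pd.DataFrame:
    op = ds.observation_period
    span = op.assign(_len=(op["observation_period_end_date"] - op["observation_period_start_date"]))
    return span.sort_values("_len").drop_duplicates("person_id", keep="last").set_index("person_id")


def _random_anchor_dates(
    ds: Dataset, persons: np.ndarray, rng: np.random.Generator, tail_days: int = 0
) -> np.ndarray:
    """A uniform random observed day per person (longest period per person),
    leaving at least ``tail_days`` of observation after the anchor."""
    best = _longest_period(ds)
    starts = best.loc[persons, "observation_period_start_date"].to_numpy()
    lens = (best.loc[persons, "_len"].to_numpy() // DAY).astype("int64") + 1 - tail_days
    if np.any(lens < 1):
        raise ValueError("some persons lack the required observation after the anchor")
    offs = np.floor(rng.random(len(persons)) * lens).astype("int64")
    return starts + offs * DAY


def extract_features(
    ds: Dataset,
    anchors: pd.DataFrame,
    excluded: ConceptSet,
    window: tuple[int, int] = (-365, 365),
    vocabulary: list[str] | None = None,
) -> tuple[sparse.csr_matrix, list[str]]:
    """Binary concept-occurrence feature matrix around per-person anchors.

    One column per ``domain:concept_id`` observed in-window, excluding every
    concept in ``excluded`` (so the phenotype's own codes cannot leak).
    Rows align with ``anchors`` (columns person_id, anchor_date). Passing a
    ``vocabulary`` pins the column set (for scoring with a trained model).
    """
    low, high = window
    ev = ds.events(("condition", "drug"))
    ev = ev[~ev["concept_id"].isin(excluded.concept_ids)]
    rows = anchors.reset_index(drop=True).reset_index(names="_row")
    merged = ev.merge(rows[["person_id", "anchor_date", "_row"]], on="person_id", how="inner")
    delta = (merged["event_date"] - merged["anchor_date"]) // DAY
    merged = merged[(delta >= low) & (delta <= high)]
    keys = merged["domain"].str.cat(merged["concept_id"].astype(str), sep=":")
    pairs = pd.DataFrame({"_row": merged["_row"], "key": keys}).drop_duplicates()
    if vocabulary is None:
        vocabulary = sorted(pairs["key"].unique())
    col_of = {k: j for j, k in enumerate(vocabulary)}
    pairs = pairs[pairs["key"].isin(col_of)]
    data = np.ones(len(pairs), dtype=np.float64)
    mat = sparse.coo_matrix(
        (data, (pairs["_row"].to_numpy(), pairs["key"].map(col_of).to_numpy())),
        shape=(len(rows), len(vocabulary)),
    ).tocsr()
    return mat, list(vocabulary)


def fit_diagnostic_model(features, labels, Cs=(0.1, 1.0, 10.0), cv: int = 3, seed: int = 0):
    """Fit the regularized logistic diagnostic model.

    Regularization strength is chosen by small internal cross-validation on
    log-loss. Deterministic given data and seed.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("diagnostic model needs both classes present")
    import inspect

    kwargs = dict(
        Cs=list(Cs),
        cv=cv,
        scoring="neg_log_loss",
        solver="lbfgs",
        max_iter=2000,
        random_state=seed,
    )
    # ridge penalty, spelled per sklearn version (penalty= is deprecated in 1.8+)
    accepted = inspect.signature(LogisticRegressionCV).parameters
    if "l1_ratios" in accepted:
        kwargs["l1_ratios"] = (0.0,)
    else:
        kwargs["penalty"] = "l2"
    if "use_legacy_attributes" in accepted:
        kwargs["use_legacy_attributes"] = False
    model = LogisticRegressionCV(**kwargs)
    model.fit(features, labels)
    return model


def predict_disease_probability(model, features) -> np.ndarray:
    """Per-person probability of truly having the disease, in [0, 1]."""
    return model.predict_proba(features)[:, 1]


def probabilistic_confusion(in_cohort, p) -> PerformanceMetrics:
    """Expected confusion matrix from membership and disease probabilities.

    Degenerates exactly to the classical confusion matrix when p is 0/1.
    """
    in_cohort = np.asarray(in_cohort, dtype=bool)
    p = np.asarray(p, dtype=float)
    if in_cohort.shape != p.shape:
        raise ValueError(f"length mismatch: {in_cohort.shape} vs {p.shape}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return PerformanceMetrics(
        tp=float(p[in_cohort].sum()),
        fp=float((1.0 - p[in_cohort]).sum()),
        fn=float(p[~in_cohort].sum()),
        tn=float((1.0 - p[~in_cohort]).sum()),
    )


@dataclass(frozen=True)
class EvalConfig:
    """Configuration of the probabilistic evaluation pipeline."""

    xspec_min_codes: int = 5
    negatives_per_xspec: float = 10.0
    eval_sample_size: int = 25_000
    feature_window: tuple[int, int] = (-365, 365)
    #: persons must have this much observation after their anchor date to be
    #: evaluable — without post-anchor data a chart-review-free reference has
    #: no evidence to classify them on
    min_days_after_anchor: int = 180
    n_bootstrap: int = 500
    seed: int = 0


@dataclass
class EvaluationResult:
    """Metrics plus the per-person probabilistic reference used to get them."""

    metrics: PerformanceMetrics
    reference: pd.DataFrame  # person_id, anchor_date, p_disease, in_cohort
    cohort: Cohort
    xspec_size: int
    n_negatives: int

    @property
    def eval_person_ids(self) -> set:
        return set(self.reference["person_id"])


def evaluate_algorithm(
    ds: Dataset, defn: CohortDefinition, config: EvalConfig = EvalConfig()
) -> EvaluationResult:
    """Full pipeline: xSpec + negatives -> model -> probabilistic confusion.

    The evaluation sample is drawn uniformly from all evaluable persons
    except xSpec members (their near-certain status would make the
    reference circular). Evaluable means at least ``min_days_after_anchor``
    days of observation follow the anchor date: the anchor is the first
    qualifying code for code-carrying persons and a random in-observation
    day otherwise. 95% intervals come from a percentile bootstrap over the
    evaluation sample.
    """
    ss = np.random.SeedSequence(config.seed).spawn(3)
    rng_neg, rng_eval, rng_boot = (np.random.default_rng(s) for s in ss)
    cs = defn.concept_set

    cohort = build_cohort(ds, defn)
    xspec = build_xspec_cohort(ds, cs, config.xspec_min_codes)
    if len(xspec) == 0:
        raise ValueError("xSpec cohort is empty; dataset too small or codes too sparse")
    n_neg = int(round(config.negatives_per_xspec * len(xspec)))
    negatives = build_negative_sample(ds, cs, n_neg, rng_neg, config.min_days_after_anchor)

    train_anchors = pd.concat(
        [
            xspec.table.rename(columns={"cohort_start_date": "anchor_date"})[["person_id", "anchor_date"]],
            negatives[["person_id", "anchor_date"]],
        ],
        ignore_index=True,
    )
    y = np.concatenate([np.ones(len(xspec)), np.zeros(len(negatives))])
    X_train, vocab = extract_features(ds, train_anchors, cs, config.feature_window)
    model = fit_diagnostic_model(X_train, y, seed=config.seed)

    # evaluation sample: evaluable persons except xSpec, uniformly subsampled
    tail = np.timedelta64(config.min_days_after_anchor, "D")
    first_code = (
        qualifying_events(ds, cs).drop_duplicates("person_id").set_index("person_id")["event_date"]
    )
    spans = _longest_period(ds)
    persons = ds.person["person_id"]
    fc = persons.map(first_code)
    p_end = persons.map(spans["observation_period_end_date"])
    p_len = persons.map(spans["_len"])
    evaluable = np.where(
        fc.notna(), (p_end - fc) >= tail, p_len >= tail
    )
    pool = persons[evaluable & ~persons.isin(xspec.person_ids)].to_numpy()
    size = min(config.eval_sample_size, len(pool))
    sample = np.sort(rng_eval.choice(pool, size=size, replace=False))

    has_code = pd.Index(sample).isin(first_code.index)
    anchors = np.empty(size, dtype="datetime64[ns]")
    anchors[has_code] = first_code.loc[sample[has_code]].to_numpy()
    anchors[~has_code] = _random_anchor_dates(ds, sample[~has_code], rng_eval, config.min_days_after_anchor)
    eval_anchors = pd.DataFrame({"person_id": sample, "anchor_date": anchors})

    X_eval, _ = extract_features(ds, eval_anchors, cs, config.feature_window, vocabulary=vocab)
    p = predict_disease_probability(model, X_eval)
    in_cohort = eval_anchors["person_id"].isin(cohort.person_ids).to_numpy()

    metrics = probabilistic_confusion(in_cohort, p)
    metrics.cis = _bootstrap_cis(in_cohort, p, config.n_bootstrap, rng_boot)
    reference = eval_anchors.assign(p_disease=p, in_cohort=in_cohort)
    return EvaluationResult(
        metrics=metrics, reference=reference, cohort=cohort,
        xspec_size=len(xspec), n_negatives=len(negatives),
    )


def _bootstrap_cis(
    in_cohort: np.ndarray, p: np.ndarray, n_boot: int, rng: np.random.Generator
) -> dict[str, tuple[float, float]]:
    """Percentile-bootstrap 95% intervals over the evaluation sample."""
    n = len(p)
    if n == 0 or n_boot == 0:
        return {}
    stats = {m: np.empty(n_boot) for m in METRIC_NAMES}
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        mb = probabilistic_confusion(in_cohort[idx], p[idx])
        for m in METRIC_NAMES:
            stats[m][b] = mb.metric(m)
    return {
        m: (float(np.nanpercentile(v, 2.5)), float(np.nanpercentile(v, 97.5)))
        for m, v in stats.items()
    }
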