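# Methods

This note records the models, conventions and design choices behind
phenoforge, in the order data flows through the package.

## Data model

Five pandas tables mirror OMOP CDM names and snake_case columns (person,
observation_period, visit_occurrence, condition_occurrence,
drug_exposure). Dates are calendar dates; every interval is measured in
whole days with actual calendar-day arithmetic. Concept identifiers are
opaque integers; the shipped HS concept set holds the two identifiers
used in practice for HS (4241223, the SNOMED-mapped "hidradenitis
suppurativa" / ICD-10 L73.2 concept, and 434119, "hidradenitis" /
ICD-9 705.83), with no vocabulary-hierarchy expansion. Events dated
outside every observation period of their person are retained on load and
flagged by the validator, but ignored by all cohort logic — claims data
genuinely contain such records, and a report-only validator keeps loading
side-effect-free. Multiple observation periods per person are treated
independently; no gap-merging rule is applied.

## Cohort-engine semantics

The executable definition has five knobs: concept set, incident flag,
washout days, minimum code count N, and a confirmation day-window
[low, high]. Fixed conventions:

* Same-day duplicate codes collapse to one qualifying day (a single
  encounter must not confirm itself); two distinct concepts on one day
  count once.
* Washout requires `index − period_start ≥ washout_days` **within one
  observation period**: an enrollment gap breaks continuity.
* Incident = the first-ever qualifying day across all periods is the only
  candidate; if it fails washout or confirmation, the person is excluded
  outright. Deferring to a later code would make the cohort non-incident.
* Confirmation codes (N−1 of them) must fall in [low, high] days after
  entry, endpoints inclusive, inside the entry's observation period — a
  disenrolled patient cannot contribute claims.
* Prevalent = the earliest qualifying day satisfying washout (trivially,
  0) and confirmation wins.
* The index date is the **entry code's** date. For two-code algorithms
  published descriptions are ambiguous between the first code and the
  date all criteria are met; characterization windows phrased as "31–365
  days after index" only make sense anchored at the first code, so that
  is the default, with `index_at="confirmation"` available. Cohort exit
  is the end of the enclosing observation period.

The four standard HS algorithms instantiate these as
incident/prevalent × N∈{1,2}, washout 365/0, window [31, 365]; the
≥N-code ladder rebuilds a base definition at N = 2, 3, … . A brute-force
per-person interpreter (pure-python date loops, no shared code) serves as
the engine's oracle in the tests.

## Synthetic data generator

Per person: one enrollment span inside the study window (start uniform;
duration exponential with configurable mean, 30-day floor, clipped to the
window); sex and birth year from simple marginals. Visits follow a
homogeneous Poisson process at `visit_rate`/year, multiplied by
`case_visit_multiplier` after disease onset. Disease truth is a mix of
*prevalent* cases (probability `baseline_prevalence`, onset 1–5 years
before enrollment) and *incident* onsets (uniform hazard
`annual_incidence`/100,000 per observed person-year). Coding is
imperfect per visit: a post-onset visit of a case carries an HS code with
probability `coding_sensitivity`; a visit of a non-case with probability
`coding_fp_rate`. Comorbidity/drug concepts are emitted per visit with a
baseline probability, multiplied on post-onset case visits by a
concept-specific rate ratio. One named random stream per table derives
from a single seed, so output is bit-reproducible and stable under
parameter changes.

What it does **not** emulate: disease course (Hurley stages, flares),
code migration across calendar time, provider/site effects, correlated
multi-morbidity beyond the per-concept rate ratios, and re-enrollment
gaps. Passing tests therefore demonstrate correctness of the machinery
and recoverability under this generative model, not performance claims
about any real database.

### Presets

* `ccae_like` — realistic commercial-claims magnitudes: 4 visits/yr,
  incidence 12/100,000 PY, prevalence 5×10⁻⁴, coding sensitivity 0.35,
  false-positive coding 2×10⁻⁵/visit, 51% female.
* `validation_like` — the evaluation workbench. At true HS rarity a
  50,000-person database yields ~10 cases; no estimator can recover PPV
  or sensitivity to ±0.10 from that. This preset keeps the claims-process
  structure but raises prevalence to 0.04, incidence to 600/100,000 PY,
  false-positive coding to 3×10⁻⁴/visit and the post-onset visit
  multiplier to 3, and makes the treatment-pattern concepts
  (clindamycin-like, doxycycline-like, recurrent skin-abscess-like,
  acne-like) strongly disease-specific. Power reasoning: with ~25,000
  evaluated persons and ~1,200 true cases, binomial noise on PPV and
  sensitivity is ≈ 0.015–0.03, leaving headroom inside a ±0.10 recovery
  band for the evaluator's structural biases; with fewer than ~200 cases
  the noise alone would exceed the band. These knobs are documented
  tuning choices of the synthetic study conditions, not empirical claims
  about HS coding.

## Probabilistic evaluation

Pipeline per algorithm: xSpec cohort (≥ 5 distinct-day codes; noisy
positives, anchored at the first code) and 10× as many code-free persons
(noisy negatives, random in-observation anchors) train an L2-regularized
logistic model (`LogisticRegressionCV`, C ∈ {0.1, 1, 10}, 3-fold CV on
log-loss) on binary concept-occurrence features within ±365 days of the
anchor, with the phenotype's own concepts excluded so the evaluated codes
cannot leak into the reference. The model scores an evaluation sample of
up to 25,000 persons drawn from everyone except xSpec members; expected
confusion-matrix cells are probability sums, and 95% intervals come from
a 500-resample percentile bootstrap over the evaluation sample.

Evaluability: a person enters the evaluation (or negative) sample only if
≥ 180 days of observation follow their anchor date. A subject whose
enrollment ends immediately after their first code leaves no post-anchor
evidence at all; no chart-review-free reference can classify them, and
including them biases PPV estimates downward. Metrics therefore refer to
the evaluable subpopulation, and the ground-truth oracle in the tests is
computed on exactly the same person set.

Known limitations: the reference model's probabilities inherit the
xSpec-vs-code-free sampling design, so they are not population-calibrated
in general; recovery to ±0.10 holds under the `validation_like`
conditions (measured across several seeds at n = 50,000, worst observed
deviation 0.08) and degrades as features lose disease specificity or
cases become rare.

## Diagnostics conventions

* Incidence denominators: at-risk time of all persons = observation time
  after the first `washout_days` of each period, clipped to the analysis
  window, censored at the person's index date (inclusive day counts,
  365.25 days/year). A person cannot index during washout, so that time
  is not at risk. Numerators are index dates in the window. Age = calendar
  year − birth year, banded 0–9 … 70–79, 80+. Zero person-time strata
  report NaN rates rather than dividing by zero.
* Standardized difference of proportions: the **unpooled** form
  `(p1−p2)/√(p1(1−p1)+p2(1−p2))` is the default because the published
  comparisons this package reproduces (0.66 from 0.50 vs 0.11; 0.3 from
  0.32 vs 0.14) follow the unpooled form; the pooled variant (dividing
  the variance sum by 2) is selectable. Degenerate p1 = p2 ∈ {0, 1}
  returns 0. Imbalance is flagged at |d| > 0.1, strictly.
* Characterization covariates are binary any-occurrence indicators per
  condition/drug concept in a day-window relative to index (default
  31–365), so proportions are invariant to event duplication.

## Published-metrics fixture

`data/published_validation_metrics.csv` transcribes the per-database
point estimates and 95% CIs (sensitivity, PPV, specificity, NPV; four
algorithms × five US databases) of a published multi-database validation
of these algorithms. Cross-database summaries are unweighted means of
point estimates, rounded half away from zero when printed as whole
percent. Three of the source's printed means (prevalent 1x sensitivity
58%, prevalent 1x PPV 59%, incident 1x sensitivity 32%) differ by one
point from the mean of its own printed cells (58.9 → 59, 59.8 → 60,
32.7 → 33), presumably computed on unrounded values; they are documented
here and deliberately not asserted anywhere.

## Pipeline and configuration

`phenoforge run --config run.yaml` executes simulate → cohorts →
diagnostics → evaluation → report into one output directory with a
manifest (version, seed, parameters). Config keys: `seed` (required),
`output_dir` (required), `simulation` (`preset` plus any
`SimulationParams` override), `diagnostics` (`incidence_window`,
`characterization_window`), `evaluation` (any `EvalConfig` field except
seed), `evaluate_algorithms`. All stage randomness derives from the one
seed; identical configs give byte-identical metrics. Stages write their
artifacts before the next begins, so failures retain partial output.

## Problem sizes in the shipped tests

Unit and property tests run on hand-built fixtures and simulations of
500–30,000 persons; the evaluator recovery check uses one 50,000-person
`validation_like` simulation. These sizes were chosen so the full suite
completes in about a minute on a single CPU while leaving every
statistical check at least ~50 expected events.
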