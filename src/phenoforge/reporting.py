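"""Cross-database metric aggregation and run reporting.

Ships a fixture of published multi-database validation estimates for the
four HS phenotype algorithms (point estimates and 95% CIs of sensitivity,
PPV, specificity and NPV across five US databases, as printed by the source
validation study). The aggregation here is the unweighted arithmetic mean
of point estimates across databases, rounded half away from zero when
expressed in whole percent.

Note on the fixture: three of the printed cross-database means (prevalent
one-code sensitivity 58%, prevalent one-code PPV 59%, incident one-code
sensitivity 32%) differ by one percentage point from the mean of the
printed per-database cells (58.9% -> 59%, 59.8% -> 60%, 32.7% -> 33%),
presumably because they were computed on unrounded values. Those three are
therefore documented, not asserted; all other printed means reproduce
exactly from the cells.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .metrics import METRIC_NAMES, PerformanceMetrics

__all__ = [
    "load_published_metrics",
    "mean_across_databases",
    "as_whole_percent",
    "ppv_ladder_report",
    "render_report",
]

ALGORITHMS = ("incident_1x", "incident_2x", "prevalent_1x", "prevalent_2x")


def load_published_metrics() -> pd.DataFrame:
    """The packaged per-database validation-metric fixture."""
    with resources.files("phenoforge.data").joinpath("published_validation_metrics.csv").open() as fh:
        return pd.read_csv(fh)


def mean_across_databases(table: pd.DataFrame, algorithm: str, metric: str) -> float:
    """Unweighted mean of a metric's point estimates across databases."""
    if metric not in METRIC_NAMES:
        raise KeyError(f"unknown metric {metric!r}")
    rows = table[table["algorithm"] == algorithm]
    if rows.empty:
        raise KeyError(f"no rows for algorithm {algorithm!r}")
    return float(rows[metric].mean())


def as_whole_percent(x: float) -> int:
    """Round a proportion to whole percent, half away from zero."""
    scaled = x * 100.0
    import math

    return int(math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1))


def ppv_ladder_report(ladder: dict[int, "PerformanceMetrics | float"]) -> tuple[pd.DataFrame, bool]:
    """(N, PPV) table for a >=N-codes ladder plus a monotonicity flag.

    Accepts PerformanceMetrics values or bare PPV floats. The flag is True
    when PPV is non-decreasing in N.
    """
    if len(ladder) < 2:
        raise ValueError("ladder needs at least 2 points")
    rows = []
    for n in sorted(ladder):
        v = ladder[n]
        ppv = v.ppv if isinstance(v, PerformanceMetrics) else float(v)
        rows.append({"min_codes": n, "ppv": ppv})
    df = pd.DataFrame(rows)
    monotone = bool((df["ppv"].diff().dropna() >= 0).all())
    return df, monotone


REPORT_ARTIFACTS = {
    "manifest": "manifest.json",
    "cohort counts": "diagnostics/cohort_counts.csv",
    "overlap": "diagnostics/overlap.csv",
    "incidence": "diagnostics/incidence.csv",
    "metrics": "metrics.csv",
}


def render_report(run_dir: str | Path) -> str:
    """Deterministic markdown summary of a pipeline run directory."""
    run_dir = Path(run_dir)
    missing = [rel for rel in REPORT_ARTIFACTS.values() if not (run_dir / rel).exists()]
    if missing:
        raise FileNotFoundError(f"run directory {run_dir} is missing artifacts: {', '.join(missing)}")
    manifest = json.loads((run_dir / "manifest.json").read_text())
    counts = pd.read_csv(run_dir / "diagnostics/cohort_counts.csv")
    overlap = pd.read_csv(run_dir / "diagnostics/overlap.csv")
    incidence = pd.read_csv(run_dir / "diagnostics/incidence.csv")
    metrics = pd.read_csv(run_dir / "metrics.csv")

    lines = ["# Phenotype-algorithm run summary", ""]
    lines += [f"- seed: {manifest.get('seed')}", f"- persons simulated: {manifest.get('n_persons')}", ""]
    lines += ["## Cohort counts", "", counts.to_csv(index=False).rstrip(), ""]
    lines += ["## Cohort overlap (person sets)", "", overlap.to_csv(index=False).rstrip(), ""]
    overall = incidence[incidence["stratum_type"] == "overall"]
    if len(overall):
        rate = overall["rate_per_100k"].iloc[0]
        lines += [f"## Incidence", "", f"Overall entry rate: {rate:.1f} per 100,000 person-years", ""]
    lines += ["## Estimated performance metrics", "", metrics.to_csv(index=False).rstrip(), ""]
    return "\n".join(lines)
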