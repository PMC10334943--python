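"""End-to-end seeded pipeline: simulate -> cohorts -> diagnose -> evaluate -> report.

A :class:`RunConfig` (one YAML file with per-stage blocks) drives all
stages; every source of randomness derives from the single run seed, so an
identical config reproduces identical numerical outputs. Each stage writes
its artifacts before the next starts, so a failed run keeps its partial
outputs for inspection.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohorts import build_hs_suite, hs_definitions
from .data_model import hs_concept_set, write_cohort, write_dataset
from .diagnostics import cohort_overlap, compare_cohorts, incidence_rates
from .phevaluator import EvalConfig, evaluate_algorithm
from .reporting import render_report
from .synthetic import SimulationParams, ccae_like, simulate_population, validation_like, write_truth

__all__ = ["ConfigError", "RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("phenoforge")

PRESETS = {"ccae_like": ccae_like, "validation_like": validation_like}


class ConfigError(ValueError):
    """The run configuration is invalid; nothing has been executed."""


@dataclass
class RunConfig:
    seed: int
    output_dir: Path
    simulation: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)
    evaluate_algorithms: tuple[str, ...] = ("incident_1x", "incident_2x", "prevalent_1x", "prevalent_2x")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "seed" not in raw:
            raise ConfigError("config must set a seed")
        if "output_dir" not in raw:
            raise ConfigError("config must set output_dir")
        return cls(
            seed=int(raw["seed"]),
            output_dir=Path(raw["output_dir"]),
            simulation=dict(raw.get("simulation", {})),
            diagnostics=dict(raw.get("diagnostics", {})),
            evaluation=dict(raw.get("evaluation", {})),
            evaluate_algorithms=tuple(raw.get("evaluate_algorithms", cls.evaluate_algorithms)),
        )


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} did not parse to a mapping")
    return RunConfig.from_dict(raw)


def _simulation_params(cfg: RunConfig) -> SimulationParams:
    sim = dict(cfg.simulation)
    preset = sim.pop("preset", "validation_like")
    if preset not in PRESETS:
        raise ConfigError(f"unknown simulation preset {preset!r}; choose from {sorted(PRESETS)}")
    return PRESETS[preset](seed=cfg.seed, **sim)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    params = _simulation_params(cfg)  # validate before touching disk
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    try:
        log.info("simulate: n_persons=%d seed=%d", params.n_persons, cfg.seed)
        ds, truth = simulate_population(params)
        write_dataset(ds, out / "data")
        write_truth(truth, out / "data" / "truth.csv")

        log.info("cohorts: building the four standard HS algorithms")
        suite = build_hs_suite(ds)
        (out / "cohorts").mkdir(exist_ok=True)
        for name, cohort in suite.items():
            write_cohort(cohort, out / "cohorts" / f"{name}.csv")

        log.info("diagnostics")
        diag_dir = out / "diagnostics"
        diag_dir.mkdir(exist_ok=True)
        pd.DataFrame(
            [{"cohort": n, "n_persons": len(c)} for n, c in suite.items()]
        ).to_csv(diag_dir / "cohort_counts.csv", index=False)
        ov = cohort_overlap(suite["incident_1x"], suite["incident_2x"])
        pd.DataFrame(
            [{"a": "incident_1x", "b": "incident_2x", "only_a": ov.only_a, "both": ov.both, "only_b": ov.only_b}]
        ).to_csv(diag_dir / "overlap.csv", index=False)
        window = tuple(cfg.diagnostics.get("incidence_window", (params.study_start, params.study_end)))
        incidence_rates(suite["incident_2x"], ds, window=window).to_csv(diag_dir / "incidence.csv", index=False)
        char_window = tuple(cfg.diagnostics.get("characterization_window", (31, 365)))
        compare_cohorts(suite["incident_1x"], suite["incident_2x"], ds, window=char_window).to_csv(
            diag_dir / "comparison.csv", index=False
        )

        log.info("evaluate: probabilistic validation")
        eval_cfg = EvalConfig(seed=cfg.seed, **cfg.evaluation)
        defs = hs_definitions()
        rows = []
        for name in cfg.evaluate_algorithms:
            res = evaluate_algorithm(ds, defs[name], eval_cfg)
            rows.append({"algorithm": name, **res.metrics.as_dict()})
        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)

        manifest = {
            "phenoforge_version": __version__,
            "seed": cfg.seed,
            "n_persons": params.n_persons,
            "simulation": {**dataclasses.asdict(params), "comorbidity_spec": len(params.comorbidity_spec)},
            "evaluation": dataclasses.asdict(eval_cfg),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

        (out / "report.md").write_text(render_report(out))
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
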