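"""Confusion-matrix container shared by the exact and probabilistic evaluators.

Cells are non-negative reals: integers for a classical chart-review-style
matrix, fractional expected counts when each person contributes their
disease probability p to the positive cells and 1-p to the negative cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["PerformanceMetrics"]

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv")


@dataclass
class PerformanceMetrics:
    """Expected-count confusion matrix with derived accuracy metrics.

    ``cis`` optionally maps metric name -> (low, high) 95% interval.
    Metrics with a zero denominator are ``nan``.
    """

    tp: float
    fp: float
    fn: float
    tn: float
    cis: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cell in ("tp", "fp", "fn", "tn"):
            if getattr(self, cell) < 0:
                raise ValueError(f"{cell} must be non-negative")

    @property
    def n(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    @staticmethod
    def _ratio(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    def metric(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(f"unknown metric {name!r}")
        return getattr(self, name)

    def as_dict(self) -> dict:
        out = {c: getattr(self, c) for c in ("tp", "fp", "fn", "tn")}
        for m in METRIC_NAMES:
            out[m] = self.metric(m)
            if m in self.cis:
                out[f"{m}_ci_low"], out[f"{m}_ci_high"] = self.cis[m]
        return out
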