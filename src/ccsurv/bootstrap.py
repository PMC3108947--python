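"""Design-aware bootstrap percentile confidence intervals.

Subjects are resampled with replacement independently within each
(case status x design stratum) cell, preserving cell sizes, so replicate
samples respect both the stratified subcohort sampling and the complete
case ascertainment of the case-cohort design.  Design weights and
counting-process rows are rebuilt on every replicate, and any model
fitting inside the statistic (including re-estimation of z-transform
moments) is repeated, so standardization uncertainty propagates into the
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from .coxfit import ConvergenceError, SeparationError
from .design import CaseCohortSample, compute_weights

__all__ = ["BootstrapPlan", "BootstrapResult", "bootstrap_ci", "resample"]


@dataclass(frozen=True)
class BootstrapPlan:
    B: int = 999
    level: float = 0.95
    seed: int = 0
    max_failure_rate: float = 0.05

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")


@dataclass
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    replicates: np.ndarray
    n_failed: int


def _cells(sample: CaseCohortSample) -> list[np.ndarray]:
    idx = sample.data.groupby(["is_case", "stratum"], sort=True).indices
    return [np.asarray(v) for v in idx.values()]


def _resample_from_cells(sample: CaseCohortSample, cells: list[np.ndarray],
                         rng: np.random.Generator) -> CaseCohortSample:
    idx = np.concatenate([cell[rng.integers(0, len(cell), len(cell))]
                          for cell in cells])
    boot = sample.data.iloc[idx].reset_index(drop=True)
    boot["uid"] = np.arange(len(boot))  # duplicated subjects count as distinct
    rep = replace(sample, data=boot, rows=None)
    return compute_weights(rep, sample.design.scheme)


def resample(sample: CaseCohortSample, rng: np.random.Generator) -> CaseCohortSample:
    """One bootstrap replicate: resample subjects within each
    (case status x stratum) cell with replacement, preserving cell sizes."""
    return _resample_from_cells(sample, _cells(sample), rng)


def bootstrap_ci(statistic: Callable[[CaseCohortSample], float],
                 sample: CaseCohortSample,
                 plan: BootstrapPlan = BootstrapPlan()) -> BootstrapResult:
    """Percentile bootstrap CI of ``statistic`` under the sampling design.

    CI endpoints are the empirical (alpha/2, 1-alpha/2) quantiles of the
    replicate values (type-7 rule; no normal approximation).  Replicates
    on which the statistic fails to converge are dropped and counted; an
    error is raised if more than ``max_failure_rate`` of them fail.
    """
    est = float(statistic(sample))
    if not np.isfinite(est):
        raise ValueError("statistic is non-finite on the original sample")
    rng = np.random.default_rng(plan.seed)
    cells = _cells(sample)
    values, n_failed = [], 0
    for _ in range(plan.B):
        rep = _resample_from_cells(sample, cells, rng)
        try:
            values.append(float(statistic(rep)))
        except (ConvergenceError, SeparationError, ValueError):
            n_failed += 1
    if not values:
        raise RuntimeError("all bootstrap replicates failed")
    if n_failed > plan.max_failure_rate * plan.B:
        raise RuntimeError(
            f"{n_failed}/{plan.B} bootstrap replicates failed "
            f"(> {plan.max_failure_rate:.0%})")
    vals = np.asarray(values)
    a = (1.0 - plan.level) / 2.0
    lo, hi = np.quantile(vals, [a, 1.0 - a], method="linear")
    return BootstrapResult(estimate=est, ci_low=float(lo), ci_high=float(hi),
                           replicates=vals, n_failed=n_failed)
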