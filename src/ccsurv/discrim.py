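"""Censoring- and design-adjusted accuracy measures for 10-year risk.

Four measures compare prediction models at a fixed horizon tau:

* AUC(tau) — probability that a subject with an event by tau receives a
  higher predicted risk than an event-free subject, estimated with
  inverse-probability-of-censoring weights (IPCW) so that subjects
  censored before tau contribute no outcome information but are
  represented through the reweighting of observable subjects;
* delta AUC — difference of AUC(tau) between two models;
* IDI — difference of discrimination slopes (mean predicted risk in
  tau-cases minus tau-controls);
* NRI — net reclassification across a fixed risk-category grid (default
  cut points 3%, 8%, 15%; intervals closed on the right).

Under the case-cohort design the comparison weights multiply the IPCW
factor by design weights: tau-cases 1 (cases fully ascertained),
event-free subcohort members 1/alpha_s, event-free subjects outside the
subcohort 0 (the subcohort already represents the event-free population).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CaseCohortSample
from .coxfit import CoxFit, predict_risk, delta_aic as _delta_aic

__all__ = [
    "NriCategories",
    "RiskPredictions",
    "DiscriminationResult",
    "weighted_km",
    "ipcw_weights",
    "tau_weights",
    "risk_predictions",
    "auc_tau",
    "delta_auc",
    "idi",
    "nri",
    "evaluate_models",
]


@dataclass(frozen=True)
class NriCategories:
    """Interior cut points of the risk-category grid (right-closed)."""

    cuts: tuple[float, ...] = (0.03, 0.08, 0.15)
    name: str = "main"

    #: sensitivity-analysis grids
    LOWER = (0.02, 0.05, 0.10)
    HIGHER = (0.05, 0.10, 0.20)

    def __post_init__(self):
        c = np.asarray(self.cuts)
        if not (np.all(np.diff(c) > 0) and np.all((c > 0) & (c < 1))):
            raise ValueError("cut points must be strictly increasing and in (0,1)")

    def assign(self, p: np.ndarray) -> np.ndarray:
        """Category index 0..len(cuts); p equal to a cut falls below it."""
        return np.searchsorted(np.asarray(self.cuts), p, side="left")


@dataclass
class RiskPredictions:
    """Predicted risks at horizon tau plus the observed outcome data."""

    model: str
    p: np.ndarray
    time: np.ndarray
    status: np.ndarray
    u: np.ndarray          # combined design x IPCW comparison weight
    tau: float

    def __post_init__(self):
        n = len(self.p)
        if not (len(self.time) == len(self.status) == len(self.u) == n):
            raise ValueError("misaligned prediction vectors")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("predicted risks must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    @property
    def is_case(self) -> np.ndarray:
        return (self.status == 1) & (self.time <= self.tau)

    @property
    def is_control(self) -> np.ndarray:
        return self.time > self.tau


def _step_eval(times: np.ndarray, values: np.ndarray, t, left: bool = False):
    """Evaluate a right-continuous step function (jumping at ``times``) at
    ``t``; ``left=True`` gives the left limit."""
    side = "left" if left else "right"
    idx = np.searchsorted(times, t, side=side)
    vals = np.concatenate([[1.0], values])
    return vals[idx]


def weighted_km(times, statuses, weights=None, *, return_steps: bool = False):
    """Weighted Kaplan-Meier survival estimator.

    S(t) = prod_{t_i <= t} (1 - sum w d_i / sum w Y_i) with weighted event
    counts and risk sets ("modified Kaplan-Meier" for the case-cohort
    design when the design weights are supplied).
    Returns (jump_times, survival) arrays, and a callable if requested.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(statuses, dtype=int)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    if len(t) == 0 or w.sum() <= 0:
        raise ValueError("no weighted subjects at risk")
    order = np.argsort(t, kind="stable")
    t, d, w = t[order], d[order], w[order]
    et, inv = np.unique(t[d == 1], return_inverse=True)
    if len(et) == 0:
        jumps, surv = np.array([]), np.array([])
    else:
        dw = np.zeros(len(et))
        np.add.at(dw, inv, w[d == 1])
        # weighted number at risk just before each event time
        total = w.sum()
        cum_w = np.cumsum(w)
        # subjects with t < et[k] have left the risk set
        left_before = np.searchsorted(t, et, side="left")
        Yw = total - np.where(left_before > 0, cum_w[left_before - 1], 0.0)
        frac = 1.0 - dw / Yw
        surv = np.cumprod(frac)
        jumps = et
    return (jumps, surv)


def km_survival_at(times, statuses, tau, weights=None, left: bool = False) -> float:
    jumps, surv = weighted_km(times, statuses, weights)
    return float(np.atleast_1d(_step_eval(jumps, surv, tau, left=left))[0])


def ipcw_weights(times, statuses, tau, weights=None) -> np.ndarray:
    """Inverse-probability-of-censoring weights for tau-horizon status.

    The censoring distribution G is the (weighted) Kaplan-Meier estimator
    with the roles of event and censoring reversed.  Subjects with an
    event by tau get 1/G(T-); subjects still under observation past tau
    get 1/G(tau); subjects censored before tau get 0.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = np.asarray(times, dtype=float)
    d = np.asarray(statuses, dtype=int)
    jumps, surv = weighted_km(t, 1 - d, weights)
    g_tau = float(np.atleast_1d(_step_eval(jumps, surv, tau))[0])
    case = (d == 1) & (t <= tau)
    control = t > tau
    if g_tau <= 0 or np.any(_step_eval(jumps, surv, t[case], left=True) <= 0):
        latest = jumps[surv > 0]
        hint = float(latest[-1]) if len(latest) else float("nan")
        raise ValueError(
            f"censoring survival reaches 0 before tau={tau}; "
            f"choose an earlier horizon (<= {hint:.3g})")
    u = np.zeros(len(t))
    u[case] = 1.0 / _step_eval(jumps, surv, t[case], left=True)
    u[control] = 1.0 / g_tau
    return u


def tau_weights(sample: CaseCohortSample, tau: float,
                mode: str = "design") -> np.ndarray:
    """Combined comparison weight u = design weight x IPCW factor.

    ``mode='design'``: tau-cases weight 1, event-free subcohort members
    1/alpha_s, event-free non-subcohort subjects 0.  ``mode='uniform'``:
    design factor 1 for all (useful on full cohorts).
    """
    data = sample.data
    t = data["time"].to_numpy(dtype=float)
    d = data["status"].to_numpy(dtype=int)
    in_sub = data["in_subcohort"].to_numpy(dtype=bool)
    alpha = data["alpha"].to_numpy(dtype=float)
    case = (d == 1) & (t <= tau)
    if mode == "design":
        base = np.where(case, 1.0, np.where(in_sub, 1.0 / alpha, 0.0))
        km_w = np.where(in_sub, 1.0 / alpha, 0.0)
        km_w = np.where(km_w > 0, km_w, np.nan)
        mask = in_sub
        ip = np.zeros(len(t))
        ip[mask] = ipcw_weights(t[mask], d[mask], tau, 1.0 / alpha[mask])
        # tau-cases outside the subcohort: same censoring distribution
        out_case = case & ~in_sub
        if out_case.any():
            jumps, surv = weighted_km(t[mask], 1 - d[mask], 1.0 / alpha[mask])
            ip[out_case] = 1.0 / _step_eval(jumps, surv, t[out_case], left=True)
    elif mode == "uniform":
        base = np.ones(len(t))
        ip = ipcw_weights(t, d, tau)
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    return base * ip


def risk_predictions(fit: CoxFit, sample: CaseCohortSample, tau: float,
                     u: np.ndarray | None = None,
                     mode: str = "design") -> RiskPredictions:
    """Predicted tau-year risks for every subject in the sample."""
    if u is None:
        u = tau_weights(sample, tau, mode)
    p = predict_risk(fit, sample.data, tau)
    return RiskPredictions(
        model=fit.spec.name, p=np.clip(p, 0.0, 1.0),
        time=sample.data["time"].to_numpy(dtype=float),
        status=sample.data["status"].to_numpy(dtype=int),
        u=np.asarray(u, dtype=float), tau=tau,
    )


def auc_tau(preds: RiskPredictions) -> float:
    """Weighted AUC at horizon tau.

    AUC = sum_{i case, j control} u_i u_j [1(p_i > p_j) + 1/2 1(p_i = p_j)]
          / sum u_i u_j, computed by an O(n log n) rank sweep equal to the
    O(n^2) pairwise definition.
    """
    case = preds.is_case & (preds.u > 0)
    ctrl = preds.is_control & (preds.u > 0)
    uc, pc = preds.u[case], preds.p[case]
    un, pn = preds.u[ctrl], preds.p[ctrl]
    if uc.sum() <= 0 or un.sum() <= 0:
        raise ValueError("need positive weighted mass of both cases and controls")
    # sweep over unique prediction values
    vals = np.unique(np.concatenate([pc, pn]))
    wc = np.zeros(len(vals))
    np.add.at(wc, np.searchsorted(vals, pc), uc)
    wn = np.zeros(len(vals))
    np.add.at(wn, np.searchsorted(vals, pn), un)
    cum_n_below = np.concatenate([[0.0], np.cumsum(wn)])[:-1]
    num = np.sum(wc * (cum_n_below + 0.5 * wn))
    return float(num / (uc.sum() * un.sum()))


def delta_auc(preds_new: RiskPredictions, preds_old: RiskPredictions) -> float:
    _check_aligned(preds_new, preds_old)
    return auc_tau(preds_new) - auc_tau(preds_old)


def _check_aligned(a: RiskPredictions, b: RiskPredictions) -> None:
    if len(a.p) != len(b.p) or a.tau != b.tau:
        raise ValueError("predictions come from different samples or horizons")
    if not (np.array_equal(a.time, b.time) and np.array_equal(a.u, b.u)):
        raise ValueError("predictions are not aligned on the same subjects")


def _slope(preds: RiskPredictions) -> float:
    case = preds.is_case
    ctrl = preds.is_control
    u = preds.u
    if u[case].sum() <= 0 or u[ctrl].sum() <= 0:
        raise ValueError("need positive weighted mass of both cases and controls")
    mc = np.sum(u[case] * preds.p[case]) / np.sum(u[case])
    mn = np.sum(u[ctrl] * preds.p[ctrl]) / np.sum(u[ctrl])
    return float(mc - mn)


def idi(preds_new: RiskPredictions, preds_old: RiskPredictions) -> float:
    """Integrated discrimination improvement: the difference between the
    two models' discrimination slopes (mean risk in cases minus controls)."""
    _check_aligned(preds_new, preds_old)
    return _slope(preds_new) - _slope(preds_old)


@dataclass
class NriResult:
    nri: float
    nri_case: float
    nri_control: float
    table_case: pd.DataFrame      # weighted counts, rows=old cat, cols=new cat
    table_control: pd.DataFrame


def nri(preds_new: RiskPredictions, preds_old: RiskPredictions,
        cats: NriCategories = NriCategories()) -> NriResult:
    """Category-based net reclassification index with 4x4 tables.

    NRI = [P_u(up|case) - P_u(down|case)]
        + [P_u(down|control) - P_u(up|control)].
    """
    _check_aligned(preds_new, preds_old)
    old = cats.assign(preds_old.p)
    new = cats.assign(preds_new.p)
    ncat = len(cats.cuts) + 1
    u = preds_new.u
    comps, tables = {}, {}
    for label, mask in (("case", preds_new.is_case),
                        ("control", preds_new.is_control)):
        total = u[mask].sum()
        if total <= 0:
            raise ValueError(f"no weighted {label}s at tau")
        up = np.sum(u[mask & (new > old)]) / total
        down = np.sum(u[mask & (new < old)]) / total
        comps[label] = (up - down) if label == "case" else (down - up)
        tab = np.zeros((ncat, ncat))
        np.add.at(tab, (old[mask], new[mask]), u[mask])
        labels = [f"cat{i + 1}" for i in range(ncat)]
        tables[label] = pd.DataFrame(tab, index=labels, columns=labels)
    return NriResult(
        nri=comps["case"] + comps["control"],
        nri_case=comps["case"], nri_control=comps["control"],
        table_case=tables["case"], table_control=tables["control"],
    )


@dataclass
class DiscriminationResult:
    """Per-model AUC(tau) and pairwise comparison statistics."""

    tau: float
    aucs: dict
    comparisons: pd.DataFrame  # new, old, delta_auc, idi, nri, nri_case, nri_control, delta_aic


def evaluate_models(sample: CaseCohortSample, fits: list[CoxFit], tau: float = 10.0,
                    cats: NriCategories = NriCategories(),
                    comparisons: list[tuple[str, str]] | None = None,
                    mode: str = "design") -> DiscriminationResult:
    """Evaluate a set of fitted models on one sample.

    ``comparisons`` lists (new_model, old_model) pairs; by default every
    model is compared with the first fit in the list.
    """
    tokens = {f.token for f in fits}
    if len(tokens) > 1:
        raise ValueError("all fits must come from the same sample")
    u = tau_weights(sample, tau, mode)
    preds = {f.spec.name: risk_predictions(f, sample, tau, u=u) for f in fits}
    by_name = {f.spec.name: f for f in fits}
    aucs = {name: auc_tau(pr) for name, pr in preds.items()}
    if comparisons is None:
        base = fits[0].spec.name
        comparisons = [(f.spec.name, base) for f in fits[1:]]
    rows = []
    for new, old in comparisons:
        res = nri(preds[new], preds[old], cats)
        rows.append({
            "new": new, "old": old,
            "auc_new": aucs[new], "auc_old": aucs[old],
            "delta_auc": aucs[new] - aucs[old],
            "idi": idi(preds[new], preds[old]),
            "nri": res.nri, "nri_case": res.nri_case,
            "nri_control": res.nri_control,
            "delta_aic": _delta_aic(by_name[new], by_name[old]).value,
        })
    return DiscriminationResult(tau=tau, aucs=aucs, comparisons=pd.DataFrame(rows))
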