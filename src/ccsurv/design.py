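"""Stratified subcohort sampling, design weights and weighted descriptives.

The case-cohort design draws a random subcohort with survey- and
sex-specific sampling fractions and adds every incident case for the
endpoint under study.  Non-cases outside the subcohort are never observed;
weighting corrects for their undersampling.

Two weighting schemes for hazard estimation are provided through a
counting-process row representation (entry, stop, status, weight):

* ``prentice`` — subcohort members are at risk throughout with weight 1;
  cases outside the subcohort enter the risk set only just before their
  own failure time.
* ``barlow`` — subcohort non-cases carry weight 1/alpha_s; subcohort cases
  carry 1/alpha_s before their event and 1 at the event; outside cases
  contribute only their event with weight 1.

Descriptive statistics always use the pure design weights (1/alpha_s on
the subcohort, 1 on outside cases), the survey-estimation convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SamplingDesign",
    "CaseCohortSample",
    "draw_subcohort",
    "as_census",
    "compute_weights",
    "weighted_descriptives",
    "spearman_matrix",
]

#: Gap (years) by which an outside case's entry precedes its failure time.
ENTRY_EPS = 1e-8

_PREVALENT_FLAG = {"diabetes": "prevalent_diabetes", "coronary": "prevalent_mi"}


@dataclass(frozen=True)
class SamplingDesign:
    """Survey- and sex-stratified sampling fractions.

    ``fractions`` is either a scalar alpha applied to every (survey, sex)
    stratum or a mapping ``{(survey, sex): alpha}`` covering all strata.
    """

    fractions: float | dict = 0.1
    scheme: str = "prentice"
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in ("prentice", "barlow"):
            raise ValueError(f"unknown weight scheme {self.scheme!r}")
        fr = self.fractions
        vals = fr.values() if isinstance(fr, dict) else [fr]
        for a in vals:
            if not 0 < a <= 1:
                raise ValueError("sampling fractions must lie in (0, 1]")

    def fraction_for(self, survey, sex) -> float:
        if isinstance(self.fractions, dict):
            try:
                return self.fractions[(survey, sex)]
            except KeyError:
                raise ValueError(f"no sampling fraction for stratum {(survey, sex)!r}")
        return self.fractions


@dataclass
class CaseCohortSample:
    """Subject-level sample (subcohort union cases) for one endpoint.

    ``data`` holds one row per subject with ``in_subcohort``, ``is_case``,
    ``stratum``, ``alpha``, ``weight_design``, and endpoint-specific
    ``time``/``status`` columns; ``rows`` holds the counting-process
    representation used by the weighted Cox fit.
    """

    data: pd.DataFrame
    endpoint: str
    design: SamplingDesign
    rows: pd.DataFrame | None = None

    @property
    def token(self) -> tuple:
        """Identity of the underlying sample, for model-comparison checks."""
        return (self.endpoint, len(self.data), self.design.scheme,
                float(self.data["weight_design"].sum()))

    @property
    def n_cases(self) -> int:
        return int(self.data["is_case"].sum())


def _subcohort_mask(cohort: pd.DataFrame, design: SamplingDesign) -> np.ndarray:
    rng = np.random.default_rng(design.seed)
    mask = np.zeros(len(cohort), dtype=bool)
    for (survey, sex), idx in cohort.groupby(["survey", "sex"], sort=True).indices.items():
        alpha = design.fraction_for(survey, sex)
        n_s = len(idx)
        if n_s == 0:
            raise ValueError(f"stratum {(survey, sex)!r} has no subjects")
        k = int(round(alpha * n_s))
        if k < 1:
            raise ValueError(
                f"stratum {(survey, sex)!r}: alpha*N = {alpha * n_s:.3g} < 1"
            )
        mask[rng.choice(idx, size=k, replace=False)] = True
    return mask


def draw_subcohort(cohort: pd.DataFrame, design: SamplingDesign,
                   endpoint: str) -> CaseCohortSample:
    """Draw the case-cohort sample for one endpoint.

    The subcohort membership is a stratified simple random sample without
    replacement of size round(alpha_s * N_s) per (survey, sex) stratum,
    drawn on the full cohort from the design seed alone — so both
    endpoints share one subcohort.  Subjects with the endpoint's prevalent
    condition are then excluded, and all incident cases appended.
    """
    tcol, scol = f"time_{endpoint}", f"status_{endpoint}"
    if tcol not in cohort.columns or scol not in cohort.columns:
        raise ValueError(f"endpoint {endpoint!r} not present in cohort")
    cohort = cohort.reset_index(drop=True)
    in_sub = _subcohort_mask(cohort, design)

    flag = _PREVALENT_FLAG.get(endpoint)
    eligible = np.ones(len(cohort), dtype=bool)
    if flag is not None and flag in cohort.columns:
        eligible = (cohort[flag] != "yes").to_numpy()

    is_case = (cohort[scol] == 1).to_numpy() & eligible
    keep = eligible & (in_sub | is_case)

    data = cohort.loc[keep].copy()
    data["in_subcohort"] = in_sub[keep].astype(int)
    data["is_case"] = is_case[keep].astype(int)
    data["stratum"] = data["survey"].astype(str) + "|" + data["sex"].astype(str)
    data["alpha"] = [design.fraction_for(sv, sx)
                     for sv, sx in zip(data["survey"], data["sex"])]
    data["time"] = data[tcol].astype(float)
    data["status"] = data[scol].astype(int)
    if "uid" not in data.columns:
        data["uid"] = data["id"].to_numpy()
    sample = CaseCohortSample(data=data.reset_index(drop=True),
                              endpoint=endpoint, design=design)
    return compute_weights(sample, design.scheme)


def as_census(cohort: pd.DataFrame, endpoint: str) -> CaseCohortSample:
    """Treat a full cohort as a case-cohort sample with alpha = 1."""
    return draw_subcohort(cohort, SamplingDesign(fractions=1.0), endpoint)


def compute_weights(sample: CaseCohortSample, scheme: str | None = None) -> CaseCohortSample:
    """Attach descriptive design weights and counting-process rows.

    Descriptive weight: 1/alpha_s for subcohort members, 1 for outside
    cases.  The ``rows`` table encodes the chosen hazard-estimation scheme
    (see module docstring); with alpha = 1 everywhere both schemes reduce
    to the unweighted full-cohort Cox representation.
    """
    scheme = scheme or sample.design.scheme
    if scheme not in ("prentice", "barlow"):
        raise ValueError(f"unknown weight scheme {scheme!r}")
    data = sample.data.copy()
    in_sub = data["in_subcohort"].to_numpy(dtype=bool)
    status = data["status"].to_numpy(dtype=int)
    time = data["time"].to_numpy(dtype=float)
    alpha = data["alpha"].to_numpy(dtype=float)
    data["weight_design"] = np.where(in_sub, 1.0 / alpha, 1.0)

    uid = data["uid"].to_numpy()
    pre = np.maximum(time - ENTRY_EPS, 0.0)

    if scheme == "prentice":
        entry = np.where(in_sub, 0.0, pre)
        rows = pd.DataFrame({"uid": uid, "entry": entry, "stop": time,
                             "event": status, "weight": np.ones(len(data))})
    else:  # barlow
        sub_nc = in_sub & (status == 0)
        sub_case = in_sub & (status == 1)
        out_case = ~in_sub
        # pre-event segment of subcohort cases (weight 1/alpha), dropped if empty
        seg = sub_case & (pre > 0)
        parts = [
            pd.DataFrame({"uid": uid[sub_nc], "entry": 0.0, "stop": time[sub_nc],
                          "event": 0, "weight": 1.0 / alpha[sub_nc]}),
            pd.DataFrame({"uid": uid[seg], "entry": 0.0, "stop": pre[seg],
                          "event": 0, "weight": 1.0 / alpha[seg]}),
            pd.DataFrame({"uid": uid[sub_case], "entry": pre[sub_case],
                          "stop": time[sub_case], "event": 1, "weight": 1.0}),
            pd.DataFrame({"uid": uid[out_case], "entry": pre[out_case],
                          "stop": time[out_case], "event": 1, "weight": 1.0}),
        ]
        rows = pd.concat(parts, ignore_index=True)
    out = replace(sample, data=data, rows=rows,
                  design=replace(sample.design, scheme=scheme))
    return out


def _stratified_se(x: np.ndarray, w: np.ndarray, strata: np.ndarray,
                   mean: float) -> float:
    """With-replacement stratified linearization SE of the weighted mean
    (finite-population correction ignored)."""
    W = w.sum()
    z = w * (x - mean) / W
    var = 0.0
    for s in np.unique(strata):
        zs = z[strata == s]
        n_h = len(zs)
        if n_h > 1:
            var += n_h / (n_h - 1) * np.sum((zs - zs.mean()) ** 2)
    return float(np.sqrt(var))


def weighted_descriptives(sample: CaseCohortSample, variables: list[str],
                          log_scale: list[str] | None = None,
                          by_case: bool = True) -> pd.DataFrame:
    """Design-weighted means with survey-sampling SEs, by case status.

    Variables flagged in ``log_scale`` are summarized on the log scale and
    exponentiated: geometric mean with the antilog of the SE.
    """
    log_scale = set(log_scale or [])
    data = sample.data
    if "weight_design" not in data.columns:
        raise ValueError("weights not computed; call compute_weights first")
    groups = data.groupby("is_case") if by_case else [(None, data)]
    out = []
    for case, g in groups:
        w = g["weight_design"].to_numpy(dtype=float)
        strata = g["stratum"].to_numpy()
        for v in variables:
            x = g[v].to_numpy(dtype=float)
            if v in log_scale:
                if np.any(x <= 0):
                    raise ValueError(f"{v}: nonpositive values under log flag")
                lx = np.log(x)
                m = float(np.sum(w * lx) / np.sum(w))
                se = _stratified_se(lx, w, strata, m)
                est, se_out, kind = float(np.exp(m)), float(np.exp(se)), "geometric"
            else:
                m = float(np.sum(w * x) / np.sum(w))
                est, se_out, kind = m, _stratified_se(x, w, strata, m), "arithmetic"
            out.append({"variable": v, "is_case": case, "mean": est,
                        "se": se_out, "kind": kind})
    return pd.DataFrame(out)


def spearman_matrix(sample: CaseCohortSample | pd.DataFrame,
                    variables: list[str]) -> pd.DataFrame:
    """Spearman rank-correlation matrix in the random subcohort.

    Average ranks for ties; constant columns yield NaN (undefined), never 0.
    """
    df = sample.data if isinstance(sample, CaseCohortSample) else sample
    if isinstance(sample, CaseCohortSample):
        df = df[df["in_subcohort"] == 1]
    if len(df) < 3:
        raise ValueError("need at least 3 subjects for rank correlations")
    sub = df[variables].astype(float)
    corr = sub.corr(method="spearman")
    const = sub.nunique() <= 1
    for v in sub.columns[const]:
        corr.loc[v, :] = np.nan
        corr.loc[:, v] = np.nan
    return corr
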