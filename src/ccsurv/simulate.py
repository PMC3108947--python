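"""Seeded synthetic cohorts with case-cohort-analysis structure.

Emulates a multi-survey population cohort followed for two endpoints
(incident type 2 diabetes and incident coronary events): three survey
strata, right-skewed mutually correlated inflammation biomarkers,
cardiometabolic covariates, Weibull proportional-hazards event times with
an optional shared frailty linking the endpoints, and administrative
censoring with uniform entry stagger.

All marginals and effects are exact by construction so that downstream
estimators can be checked against analytic truth: biomarkers are
log-normal with stated log-scale moments, and hazards are Weibull baseline
times exp(linear predictor) with log-hazard ratios applied to analytically
standardized covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "BiomarkerSpec",
    "ContinuousCovariate",
    "CategoricalCovariate",
    "EndpointSpec",
    "CensoringSpec",
    "SimulationConfig",
    "default_config",
    "default_biomarker_corr",
    "simulate_biomarkers",
    "simulate_event_times",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "validate_cohort",
    "BIOMARKERS",
]

#: Canonical 13-marker inflammation panel (serum concentrations).
BIOMARKERS = [
    "crp", "il6", "il18", "mif", "mcp1", "il8", "ip10",
    "adiponectin", "leptin", "rantes", "tgfb1", "se_selectin", "sicam1",
]


@dataclass(frozen=True)
class BiomarkerSpec:
    """Log-normal marginal for one biomarker.

    ``bmi_loading`` is the log-scale correlation with standardized BMI;
    the marginal log-SD is preserved (the independent component is scaled
    by sqrt(1 - loading^2)), so adiposity-driven markers such as leptin
    correlate with BMI without changing their stated marginal.
    """

    name: str
    log_mean: float
    log_sd: float
    bmi_loading: float = 0.0


@dataclass(frozen=True)
class ContinuousCovariate:
    name: str
    mean: float
    sd: float


@dataclass(frozen=True)
class CategoricalCovariate:
    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...]


@dataclass(frozen=True)
class EndpointSpec:
    """Weibull proportional-hazards endpoint.

    ``log_hr`` maps covariate or biomarker names to log hazard ratios per
    1 SD (continuous; standardization uses analytic moments) or, for
    categorical covariates, to ``{level: log_hr}`` dicts with the first
    level as reference.  If ``target_incidence`` is set the Weibull scale
    is recalibrated at simulation time so that the cumulative incidence at
    ``target_horizon`` years matches it given the realized linear
    predictors.
    """

    name: str
    shape: float
    scale: float
    log_hr: dict = field(default_factory=dict)
    target_incidence: float | None = None
    target_horizon: float = 10.0

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Weibull shape and scale must be > 0")


@dataclass(frozen=True)
class CensoringSpec:
    horizon: float = 18.2        # administrative end of follow-up, years
    entry_stagger: float = 10.0  # uniform entry window, years

    def __post_init__(self):
        if self.horizon <= 0:
            raise ValueError("censoring horizon must be > 0")
        if not 0 <= self.entry_stagger < self.horizon:
            raise ValueError("entry stagger must lie in [0, horizon)")


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int
    biomarkers: tuple[BiomarkerSpec, ...]
    biomarker_corr: np.ndarray
    covariates: tuple = ()
    endpoints: tuple[EndpointSpec, ...] = ()
    n_surveys: int = 3
    sex_ratio: float = 0.5
    age_range: tuple[float, float] = (25.0, 74.0)
    frailty_sd: float = 0.3
    frailty_corr: float = 0.5
    prevalence: dict = field(default_factory=dict)
    censoring: CensoringSpec = field(default_factory=CensoringSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 < self.sex_ratio < 1:
            raise ValueError("sex_ratio must be in (0, 1)")
        if not 0 <= self.frailty_corr <= 1:
            raise ValueError("frailty_corr must be in [0, 1]")
        _check_corr(np.asarray(self.biomarker_corr, dtype=float))
        for ep in self.endpoints:
            for v in ep.log_hr.values():
                vals = list(v.values()) if isinstance(v, dict) else [v]
                if not np.all(np.isfinite(vals)):
                    raise ValueError(f"non-finite log-HR in endpoint {ep.name!r}")


def _check_corr(corr: np.ndarray) -> None:
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    w = np.linalg.eigvalsh(corr)
    if w[0] <= 1e-10:
        raise ValueError(
            f"correlation matrix is not positive definite "
            f"(smallest eigenvalue {w[0]:.3e})"
        )


def default_biomarker_corr() -> np.ndarray:
    """Default 13x13 log-scale correlation for the inflammation panel.

    A free parameter of the generator: acute-phase and chemokine markers
    share moderate positive correlations; adiponectin runs against the
    acute-phase axis and with leptin reflects the adipokine block.
    """
    p = len(BIOMARKERS)
    idx = {b: i for i, b in enumerate(BIOMARKERS)}
    corr = np.full((p, p), 0.15)
    acute = ["crp", "il6", "il18", "sicam1", "se_selectin"]
    chemo = ["mcp1", "il8", "ip10", "rantes", "mif"]
    for block, rho in ((acute, 0.35), (chemo, 0.30)):
        for a in block:
            for b in block:
                if a != b:
                    corr[idx[a], idx[b]] = rho
    for b in ("crp", "il6", "leptin"):
        corr[idx["adiponectin"], idx[b]] = -0.20
        corr[idx[b], idx["adiponectin"]] = -0.20
    corr[idx["leptin"], idx["crp"]] = corr[idx["crp"], idx["leptin"]] = 0.30
    np.fill_diagonal(corr, 1.0)
    _check_corr(corr)
    return corr


_DEFAULT_BIOMARKERS = (
    # name, log-mean, log-SD, BMI loading on the log scale
    BiomarkerSpec("crp", 0.3, 1.1, 0.30),
    BiomarkerSpec("il6", 0.6, 0.8, 0.20),
    BiomarkerSpec("il18", 5.4, 0.5, 0.10),
    BiomarkerSpec("mif", 3.2, 0.7, 0.0),
    BiomarkerSpec("mcp1", 4.9, 0.5, 0.0),
    BiomarkerSpec("il8", 1.6, 0.6, 0.0),
    BiomarkerSpec("ip10", 4.4, 0.6, 0.0),
    BiomarkerSpec("adiponectin", 2.1, 0.55, -0.25),
    BiomarkerSpec("leptin", 2.0, 0.9, 0.45),
    BiomarkerSpec("rantes", 10.0, 0.6, 0.0),
    BiomarkerSpec("tgfb1", 9.9, 0.5, 0.0),
    BiomarkerSpec("se_selectin", 3.7, 0.45, 0.15),
    BiomarkerSpec("sicam1", 5.6, 0.3, 0.10),
)

_DEFAULT_COVARIATES = (
    ContinuousCovariate("bmi", 27.3, 4.2),
    ContinuousCovariate("sbp", 132.0, 18.0),
    ContinuousCovariate("chol_ratio", 4.3, 1.1),
    CategoricalCovariate("smoking", ("never", "former", "current"), (0.45, 0.30, 0.25)),
    CategoricalCovariate("alcohol", ("none", "moderate", "high"), (0.30, 0.50, 0.20)),
    CategoricalCovariate("activity", ("low", "high"), (0.45, 0.55)),
    CategoricalCovariate("parental_diabetes", ("negative", "positive", "unknown"), (0.70, 0.20, 0.10)),
    CategoricalCovariate("parental_mi", ("negative", "positive", "unknown"), (0.72, 0.18, 0.10)),
)

# Standardized log-HRs per endpoint.  Biomarker effects span the
# protective-to-adverse range HR ~0.5-1.4 per SD; the basic-model signal
# (age, sex) is deliberately stronger for coronary events than for
# diabetes, and the cardiometabolic block carries most of the diabetes
# signal, mirroring the epidemiology the generator emulates.
_DIABETES_HR = {
    "age": 0.45,
    "sex": {"female": 0.0, "male": 0.25},
    "bmi": 0.60,
    "sbp": 0.20,
    "chol_ratio": 0.25,
    "smoking": {"never": 0.0, "former": 0.10, "current": 0.25},
    "alcohol": {"none": 0.0, "moderate": -0.10, "high": 0.15},
    "activity": {"low": 0.0, "high": -0.15},
    "parental_diabetes": {"negative": 0.0, "positive": 0.45, "unknown": 0.10},
    "il18": np.log(1.30),
    "adiponectin": np.log(0.50),
    "leptin": np.log(1.20),
    "se_selectin": np.log(1.40),
    "sicam1": np.log(1.25),
}

_CORONARY_HR = {
    "age": 0.85,
    "sex": {"female": 0.0, "male": 0.90},
    "bmi": 0.15,
    "sbp": 0.35,
    "chol_ratio": 0.35,
    "smoking": {"never": 0.0, "former": 0.15, "current": 0.55},
    "alcohol": {"none": 0.0, "moderate": -0.10, "high": 0.10},
    "activity": {"low": 0.0, "high": -0.15},
    "parental_mi": {"negative": 0.0, "positive": 0.35, "unknown": 0.05},
    "prevalent_diabetes": {"no": 0.0, "yes": 0.70},
    "il6": np.log(1.25),
    "sicam1": np.log(1.30),
}


def default_config(n_subjects: int = 13400, seed: int = 0) -> SimulationConfig:
    """Default study conditions: 3 surveys, 13-marker panel, two endpoints
    with 10-year cumulative incidence targets of 10% (diabetes) and 7%
    (coronary events), administrative censoring at 18.2 years."""
    endpoints = (
        EndpointSpec("diabetes", shape=1.3, scale=40.0,
                     log_hr=dict(_DIABETES_HR), target_incidence=0.10),
        EndpointSpec("coronary", shape=1.1, scale=60.0,
                     log_hr=dict(_CORONARY_HR), target_incidence=0.07),
    )
    return SimulationConfig(
        n_subjects=n_subjects,
        biomarkers=_DEFAULT_BIOMARKERS,
        biomarker_corr=default_biomarker_corr(),
        covariates=_DEFAULT_COVARIATES,
        endpoints=endpoints,
        prevalence={"prevalent_diabetes": 0.04, "prevalent_mi": 0.025},
        seed=seed,
    )


def simulate_biomarkers(
    n: int,
    spec: tuple[BiomarkerSpec, ...],
    corr: np.ndarray,
    seed: int | np.random.Generator,
    bmi_z: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw correlated log-normal biomarker concentrations.

    A multivariate normal is drawn on the log scale (Cholesky of ``corr``)
    and exponentiated, so Spearman correlations of the concentrations equal
    the rank correlations of the log-scale normals.  If ``bmi_z`` is given,
    markers with nonzero ``bmi_loading`` mix it in on the log scale with
    the marginal log-SD preserved.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    corr = np.asarray(corr, dtype=float)
    _check_corr(corr)
    if corr.shape[0] != len(spec):
        raise ValueError("corr dimension does not match number of biomarkers")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, len(spec))) @ L.T
    cols = {}
    for j, bm in enumerate(spec):
        zj = z[:, j]
        if bmi_z is not None and bm.bmi_loading != 0.0:
            lam = bm.bmi_loading
            zj = np.sqrt(1.0 - lam**2) * zj + lam * bmi_z
        cols[bm.name] = np.exp(bm.log_mean + bm.log_sd * zj)
    return pd.DataFrame(cols)


def simulate_event_times(
    linear_predictor: np.ndarray,
    baseline: tuple[float, float],
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Latent Weibull proportional-hazards event times in years.

    T = scale * (-log U / exp(lp))**(1/shape); the hazard is the Weibull
    baseline multiplied by exp(lp), i.e. exactly proportional hazards.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor contains non-finite values")
    shape, scale = baseline
    if shape <= 0 or scale <= 0:
        raise ValueError("Weibull shape and scale must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=lp.shape)
    return scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)


def _standardize(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return (np.asarray(values, dtype=float) - mean) / sd


def _analytic_moments(bm: BiomarkerSpec) -> tuple[float, float]:
    # moments of the log-normal concentration itself
    m = np.exp(bm.log_mean + 0.5 * bm.log_sd**2)
    v = (np.exp(bm.log_sd**2) - 1.0) * m**2
    return m, np.sqrt(v)


def _linear_predictor(df: pd.DataFrame, config: SimulationConfig,
                      ep: EndpointSpec) -> np.ndarray:
    """Assemble lp with analytic standardization so the configured log-HRs
    are the exact data-generating truth per SD."""
    lp = np.zeros(len(df))
    lo, hi = config.age_range
    cont_moments = {"age": ((lo + hi) / 2.0, (hi - lo) / np.sqrt(12.0))}
    for cov in config.covariates:
        if isinstance(cov, ContinuousCovariate):
            cont_moments[cov.name] = (cov.mean, cov.sd)
    for bm in config.biomarkers:
        cont_moments[bm.name] = _analytic_moments(bm)
    for name, eff in ep.log_hr.items():
        if isinstance(eff, dict):
            lp += df[name].map(eff).to_numpy(dtype=float)
        else:
            m, s = cont_moments[name]
            lp += eff * _standardize(df[name].to_numpy(), m, s)
    return lp


def _calibrate_scale(ep: EndpointSpec, lp: np.ndarray) -> float:
    """Solve the Weibull scale so mean P(T <= horizon | lp) hits the target."""
    tau, q = ep.target_horizon, ep.target_incidence
    elp = np.exp(lp)

    def inc(log_scale):
        return np.mean(1.0 - np.exp(-((tau / np.exp(log_scale)) ** ep.shape) * elp)) - q

    return float(np.exp(optimize.brentq(inc, np.log(1e-2), np.log(1e4))))


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a full cohort table with both endpoints.

    Deterministic under a fixed config (single seeded generator, fixed
    draw order).  Observed time = min(latent event time, administrative
    censoring time); censoring time = horizon − uniform entry stagger.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    df = pd.DataFrame({"id": np.arange(1, n + 1)})
    df["survey"] = np.array([f"S{i + 1}" for i in rng.integers(0, config.n_surveys, n)])
    df["sex"] = np.where(rng.uniform(size=n) < config.sex_ratio, "male", "female")
    lo, hi = config.age_range
    df["age"] = rng.uniform(lo, hi, n)

    bmi_z = None
    for cov in config.covariates:
        if isinstance(cov, ContinuousCovariate):
            df[cov.name] = rng.normal(cov.mean, cov.sd, n)
            if cov.name == "bmi":
                bmi_z = _standardize(df["bmi"].to_numpy(), cov.mean, cov.sd)
        else:
            df[cov.name] = rng.choice(cov.levels, size=n, p=cov.probs)

    bio = simulate_biomarkers(n, config.biomarkers, config.biomarker_corr, rng, bmi_z)
    df = pd.concat([df, bio], axis=1)

    for flag, prev in config.prevalence.items():
        df[flag] = np.where(rng.uniform(size=n) < prev, "yes", "no")

    # shared log-normal frailty linking the endpoints
    z_shared = rng.standard_normal(n)
    rho = config.frailty_corr
    entry = rng.uniform(0.0, config.censoring.entry_stagger, n)
    cens = config.censoring.horizon - entry

    for ep in config.endpoints:
        lp = _linear_predictor(df, config, ep)
        if config.frailty_sd > 0:
            z_own = rng.standard_normal(n)
            frail = config.frailty_sd * (rho * z_shared + np.sqrt(1 - rho**2) * z_own)
            lp = lp + frail
        scale = ep.scale if ep.target_incidence is None else _calibrate_scale(ep, lp)
        latent = simulate_event_times(lp, (ep.shape, scale), rng)
        df[f"time_{ep.name}"] = np.minimum(latent, cens)
        df[f"status_{ep.name}"] = (latent <= cens).astype(int)

    return df


# ---------------------------------------------------------------------------
# CSV round trip

def validate_cohort(df: pd.DataFrame, endpoints: list[str] | None = None) -> None:
    """Raise ValueError listing offending rows if invariants are violated."""
    if "id" not in df.columns:
        raise ValueError("missing required column 'id'")
    if df["id"].duplicated().any():
        rows = df.index[df["id"].duplicated()].tolist()[:10]
        raise ValueError(f"duplicate subject ids at rows {rows}")
    if endpoints is None:
        endpoints = [c[len("time_"):] for c in df.columns if c.startswith("time_")]
    problems = []
    for ep in endpoints:
        tcol, scol = f"time_{ep}", f"status_{ep}"
        for col in (tcol, scol):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        t = pd.to_numeric(df[tcol], errors="coerce")
        bad = df.index[~(t > 0) | t.isna()].tolist()
        if bad:
            problems.append(f"{tcol}: non-positive or non-numeric times at rows {bad[:10]}")
        s = pd.to_numeric(df[scol], errors="coerce")
        bad = df.index[~s.isin([0, 1])].tolist()
        if bad:
            problems.append(f"{scol}: non-binary statuses at rows {bad[:10]}")
    na_rows = df.index[df.isna().any(axis=1)].tolist()
    if na_rows:
        problems.append(f"missing values at rows {na_rows[:10]}")
    if problems:
        raise ValueError("; ".join(problems))


def write_cohort(df: pd.DataFrame, path) -> None:
    validate_cohort(df)
    # %.17g guarantees a lossless float64 round trip
    df.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating invariants; extra columns are kept."""
    df = pd.read_csv(path)
    validate_cohort(df)
    return df
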