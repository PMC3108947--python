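"""End-to-end orchestration of the two-endpoint case-cohort analysis.

For each endpoint the pipeline draws the stratified case-cohort sample,
fits the standard model ladder

* model a — age, sex, survey (basic),
* model b — a + all 13 inflammation biomarkers,
* model c — a + cardiometabolic risk factors,
* model d — c + all 13 biomarkers,
* model 1 / model 2 per biomarker — a (resp. c) + that biomarker,
* significant subset — a/c + the biomarkers with robust-Wald p < 0.05 in
  their model 2,

computes AUC(tau), delta AUC, IDI, NRI and delta AIC for the declared
comparisons, attaches stratified bootstrap percentile CIs, and writes
CSV tables, a JSON summary and a plain-text run log.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import BootstrapPlan, bootstrap_ci
from .coxfit import (ModelSpec, Term, fit_weighted_cox, hazard_ratios)
from .design import SamplingDesign, CaseCohortSample, draw_subcohort
from .discrim import (NriCategories, evaluate_models, nri, risk_predictions,
                      tau_weights, delta_auc as _delta_auc, idi as _idi)
from .simulate import BIOMARKERS, SimulationConfig, default_config, read_cohort, simulate_cohort

__all__ = ["RunConfig", "build_models", "run_full_analysis", "sensitivity_suite"]

logger = logging.getLogger("ccsurv")

_PARENTAL = {"diabetes": "parental_diabetes", "coronary": "parental_mi"}


def basic_terms() -> tuple[Term, ...]:
    return (
        Term("age"),
        Term("sex", kind="categorical", reference="female"),
        Term("survey", kind="categorical", reference="S1"),
    )


def cardiometabolic_terms(endpoint: str) -> tuple[Term, ...]:
    terms = [
        Term("bmi"),
        Term("sbp"),
        Term("chol_ratio"),
        Term("smoking", kind="categorical", reference="never"),
        Term("alcohol", kind="categorical", reference="none"),
        Term("activity", kind="categorical", reference="low"),
        Term(_PARENTAL[endpoint], kind="categorical", reference="negative"),
    ]
    if endpoint == "coronary":
        terms.append(Term("prevalent_diabetes", kind="categorical", reference="no"))
    return tuple(terms)


def biomarker_terms(biomarkers: list[str]) -> tuple[Term, ...]:
    return tuple(Term(b, zscore=True) for b in biomarkers)


def build_models(endpoint: str, biomarkers: list[str]) -> dict[str, ModelSpec]:
    """The model registry for one endpoint (a-d plus per-biomarker 1/2)."""
    a = ModelSpec("model_a", endpoint, basic_terms())
    c = ModelSpec("model_c", endpoint, basic_terms() + cardiometabolic_terms(endpoint))
    models = {
        "model_a": a,
        "model_b": a.with_terms(biomarker_terms(biomarkers), "model_b"),
        "model_c": c,
        "model_d": c.with_terms(biomarker_terms(biomarkers), "model_d"),
    }
    for b in biomarkers:
        models[f"model1_{b}"] = a.with_terms(biomarker_terms([b]), f"model1_{b}")
        models[f"model2_{b}"] = c.with_terms(biomarker_terms([b]), f"model2_{b}")
    return models


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full analysis run."""

    simulation: SimulationConfig | None = None
    cohort_path: str | None = None
    design: SamplingDesign = field(default_factory=SamplingDesign)
    endpoints: tuple[str, ...] = ("diabetes", "coronary")
    biomarkers: tuple[str, ...] = tuple(BIOMARKERS)
    tau: float = 10.0
    categories: tuple[NriCategories, ...] = (
        NriCategories(),
        NriCategories(NriCategories.LOWER, name="lower"),
        NriCategories(NriCategories.HIGHER, name="higher"),
    )
    plan: BootstrapPlan = field(default_factory=lambda: BootstrapPlan(B=199))
    bootstrap_scope: str = "panel"   # 'none' | 'panel' | 'all'
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self):
        if self.simulation is None and self.cohort_path is None:
            raise ValueError("need either a simulation config or a cohort path")
        if self.bootstrap_scope not in ("none", "panel", "all"):
            raise ValueError(f"unknown bootstrap scope {self.bootstrap_scope!r}")


def _substreams(seed: int, n: int) -> list[int]:
    """Named substreams from one master seed, each below 2**31."""
    states = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in states]


def _load_cohort(config: RunConfig) -> pd.DataFrame:
    if config.cohort_path is not None:
        return read_cohort(config.cohort_path)
    sim_seed, _ = _substreams(config.seed, 2)
    sim = replace(config.simulation, seed=sim_seed)
    return simulate_cohort(sim)


def _comparison_stat(models: dict, new: str, old: str, tau: float, stat: str):
    """Closure recomputing a pairwise statistic from scratch on a sample
    (both models refitted, z moments re-estimated)."""
    def statistic(sample: CaseCohortSample) -> float:
        f_new = fit_weighted_cox(sample, models[new])
        f_old = fit_weighted_cox(sample, models[old])
        u = tau_weights(sample, tau)
        p_new = risk_predictions(f_new, sample, tau, u=u)
        p_old = risk_predictions(f_old, sample, tau, u=u)
        return _delta_auc(p_new, p_old) if stat == "delta_auc" else _idi(p_new, p_old)
    return statistic


def _analyze_endpoint(cohort: pd.DataFrame, config: RunConfig, endpoint: str,
                      design: SamplingDesign, boot_seed: int,
                      biomarkers: list[str] | None = None) -> dict:
    biomarkers = list(biomarkers if biomarkers is not None else config.biomarkers)
    t0 = _time.perf_counter()
    sample = draw_subcohort(cohort, design, endpoint)
    logger.info("%s: sample n=%d (cases %d, subcohort %d)", endpoint,
                len(sample.data), sample.n_cases,
                int(sample.data["in_subcohort"].sum()))

    models = build_models(endpoint, biomarkers)
    fits = {name: fit_weighted_cox(sample, spec) for name, spec in models.items()}

    # forest-plot table (per-biomarker HR under both adjustment sets)
    forest = []
    for b in biomarkers:
        for mnum in (1, 2):
            hr = hazard_ratios(fits[f"model{mnum}_{b}"])
            row = hr[hr["term"] == b].iloc[0]
            forest.append({"biomarker": b, "model": mnum, "hr": row["hr"],
                           "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                           "p": row["p"]})
    forest = pd.DataFrame(forest)

    # significant-subset models: p < 0.05 for the biomarker term in model 2
    sig = [b for b in biomarkers
           if forest.query("biomarker == @b and model == 2")["p"].iloc[0] < 0.05]
    if sig:
        models["model_subset1"] = models["model_a"].with_terms(
            biomarker_terms(sig), "model_subset1")
        models["model_subset2"] = models["model_c"].with_terms(
            biomarker_terms(sig), "model_subset2")
        fits["model_subset1"] = fit_weighted_cox(sample, models["model_subset1"])
        fits["model_subset2"] = fit_weighted_cox(sample, models["model_subset2"])

    comparisons = [("model_b", "model_a"), ("model_c", "model_a"),
                   ("model_d", "model_c"), ("model_d", "model_a")]
    for b in biomarkers:
        comparisons.append((f"model1_{b}", "model_a"))
        comparisons.append((f"model2_{b}", "model_c"))
    if sig:
        comparisons += [("model_subset1", "model_a"), ("model_subset2", "model_c")]

    cats_main = config.categories[0]
    disc = evaluate_models(sample, list(fits.values()), config.tau,
                           cats=cats_main, comparisons=comparisons)

    # bootstrap percentile CIs for delta AUC and IDI
    ci_pairs: list[tuple[str, str]] = []
    if config.bootstrap_scope == "panel":
        ci_pairs = [("model_b", "model_a"), ("model_c", "model_a"),
                    ("model_d", "model_c")]
    elif config.bootstrap_scope == "all":
        ci_pairs = comparisons
    cis = {}
    for i, (new, old) in enumerate(ci_pairs):
        for stat in ("delta_auc", "idi"):
            res = bootstrap_ci(
                _comparison_stat(models, new, old, config.tau, stat),
                sample, replace(config.plan, seed=boot_seed + i))
            cis[(new, old, stat)] = res
            logger.info("%s: bootstrap %s %s vs %s: %.4f (%.4f, %.4f)",
                        endpoint, stat, new, old,
                        res.estimate, res.ci_low, res.ci_high)

    # NRI under the alternative category grids (sensitivity analysis)
    u = tau_weights(sample, config.tau)
    preds = {n: risk_predictions(fits[n], sample, config.tau, u=u) for n in fits}
    nri_grid = []
    for cats in config.categories:
        for new, old in [("model_b", "model_a"), ("model_d", "model_c")]:
            r = nri(preds[new], preds[old], cats)
            nri_grid.append({"categories": cats.name,
                             "cuts": "/".join(str(c) for c in cats.cuts),
                             "new": new, "old": old, "nri": r.nri,
                             "nri_case": r.nri_case, "nri_control": r.nri_control})
    nri_grid = pd.DataFrame(nri_grid)

    logger.info("%s: analysis finished in %.1f s", endpoint,
                _time.perf_counter() - t0)
    return {"sample": sample, "models": models, "fits": fits, "forest": forest,
            "significant": sig, "discrimination": disc, "cis": cis,
            "nri_grid": nri_grid}


def _auc_table(res: dict, biomarkers: list[str]) -> pd.DataFrame:
    """Table-1/2-style layout: per biomarker AUC under both adjustment sets."""
    comp = res["discrimination"].comparisons.set_index(["new", "old"])
    aucs = res["discrimination"].aucs
    cis = res["cis"]

    def ci_str(new, old):
        r = cis.get((new, old, "delta_auc"))
        return (r.ci_low, r.ci_high) if r is not None else (np.nan, np.nan)

    rows = [{"biomarker": "none", "auc1": aucs["model_a"], "delta_auc1": np.nan,
             "d1_lo": np.nan, "d1_hi": np.nan, "auc2": aucs["model_c"],
             "delta_auc2": np.nan, "d2_lo": np.nan, "d2_hi": np.nan}]
    entries = [(b, f"model1_{b}", f"model2_{b}") for b in biomarkers]
    entries.append(("all_13", "model_b", "model_d"))
    if res["significant"]:
        entries.append(("significant_subset", "model_subset1", "model_subset2"))
    for label, m1, m2 in entries:
        lo1, hi1 = ci_str(m1, "model_a")
        lo2, hi2 = ci_str(m2, "model_c")
        rows.append({
            "biomarker": label,
            "auc1": aucs[m1], "delta_auc1": comp.loc[(m1, "model_a"), "delta_auc"],
            "d1_lo": lo1, "d1_hi": hi1,
            "auc2": aucs[m2], "delta_auc2": comp.loc[(m2, "model_c"), "delta_auc"],
            "d2_lo": lo2, "d2_hi": hi2,
        })
    return pd.DataFrame(rows)


def _accuracy_table(res: dict, biomarkers: list[str]) -> pd.DataFrame:
    """S4/S5-style layout: delta AIC, IDI, NRI per biomarker and panel."""
    comp = res["discrimination"].comparisons.set_index(["new", "old"])
    entries = [(b, f"model1_{b}", f"model2_{b}") for b in biomarkers]
    entries.append(("all_13", "model_b", "model_d"))
    if res["significant"]:
        entries.append(("significant_subset", "model_subset1", "model_subset2"))
    rows = []
    for label, m1, m2 in entries:
        r1 = comp.loc[(m1, "model_a")]
        r2 = comp.loc[(m2, "model_c")]
        rows.append({"biomarker": label,
                     "delta_aic1": r1["delta_aic"], "idi1": r1["idi"], "nri1": r1["nri"],
                     "delta_aic2": r2["delta_aic"], "idi2": r2["idi"], "nri2": r2["nri"]})
    return pd.DataFrame(rows)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return float(x)
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_full_analysis(config: RunConfig) -> dict:
    """Run the complete two-endpoint analysis; write tables, JSON and log.

    Returns the in-memory result bundle keyed by endpoint.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = _time.perf_counter()
    try:
        logger.info("ccsurv %s | numpy %s | pandas %s | seed %d",
                    __version__, np.__version__, pd.__version__, config.seed)
        cohort = _load_cohort(config)
        logger.info("cohort: %d subjects", len(cohort))
        _, design_seed = _substreams(config.seed, 2)
        design = replace(config.design, seed=design_seed)
        boot_seeds = _substreams(config.seed + 1, len(config.endpoints) * 64)

        results, summary = {}, {"seed": config.seed, "tau": config.tau,
                                "n_cohort": len(cohort), "endpoints": {}}
        for j, endpoint in enumerate(config.endpoints):
            res = _analyze_endpoint(cohort, config, endpoint, design,
                                    boot_seeds[j * 64])
            results[endpoint] = res
            biomarkers = list(config.biomarkers)
            auc_tbl = _auc_table(res, biomarkers)
            acc_tbl = _accuracy_table(res, biomarkers)
            auc_tbl.to_csv(out / f"auc_{endpoint}.csv", index=False,
                           float_format="%.6f")
            acc_tbl.to_csv(out / f"accuracy_{endpoint}.csv", index=False,
                           float_format="%.6f")
            res["forest"].to_csv(out / f"forest_{endpoint}.csv", index=False,
                                 float_format="%.6f")
            res["nri_grid"].to_csv(out / f"nri_sensitivity_{endpoint}.csv",
                                   index=False, float_format="%.6f")
            comp = res["discrimination"].comparisons
            summary["endpoints"][endpoint] = {
                "n_sample": len(res["sample"].data),
                "n_cases": res["sample"].n_cases,
                "aucs": res["discrimination"].aucs,
                "significant_biomarkers": res["significant"],
                "comparisons": comp.to_dict(orient="records"),
                "bootstrap_cis": {
                    f"{new}_vs_{old}_{stat}": {
                        "estimate": r.estimate, "ci_low": r.ci_low,
                        "ci_high": r.ci_high}
                    for (new, old, stat), r in res["cis"].items()},
            }
        summary["elapsed_s"] = _time.perf_counter() - t0
        with open(out / "summary.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2)
        logger.info("run complete in %.1f s", summary["elapsed_s"])
    finally:
        logger.removeHandler(handler)
        handler.close()
    results["summary"] = summary
    return results


def sensitivity_suite(config: RunConfig, exclude_biomarkers: tuple[str, ...] = (),
                      substitutions: dict[str, str] | None = None) -> dict:
    """Sensitivity re-analysis: biomarker exclusion, alternative NRI grids
    and covariate substitution; reports deltas against the base run.

    ``substitutions`` maps a model covariate to a replacement cohort
    column (e.g. BMI -> waist circumference).
    """
    for b in exclude_biomarkers:
        if b not in config.biomarkers:
            raise ValueError(f"unknown biomarker {b!r}")
    base = run_full_analysis(replace(config, bootstrap_scope="none",
                                     out_dir=str(Path(config.out_dir) / "base")))
    reduced = [b for b in config.biomarkers if b not in exclude_biomarkers]
    report = {"excluded": list(exclude_biomarkers), "endpoints": {}}
    cohort = _load_cohort(config)
    if substitutions:
        cohort = cohort.rename(columns={v: k for k, v in substitutions.items()})
    _, design_seed = _substreams(config.seed, 2)
    design = replace(config.design, seed=design_seed)
    for endpoint in config.endpoints:
        res = _analyze_endpoint(cohort, replace(config, bootstrap_scope="none"),
                                endpoint, design, 0, biomarkers=reduced)
        base_aucs = base[endpoint]["discrimination"].aucs
        aucs = res["discrimination"].aucs
        report["endpoints"][endpoint] = {
            "auc_model_b": aucs["model_b"], "auc_model_d": aucs["model_d"],
            "delta_vs_base_model_b": aucs["model_b"] - base_aucs["model_b"],
            "delta_vs_base_model_d": aucs["model_d"] - base_aucs["model_d"],
            "nri_grid": res["nri_grid"].to_dict(orient="records"),
        }
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "sensitivity.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    return report
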