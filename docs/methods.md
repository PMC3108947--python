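# Methods

`ccsurv` implements a design-weighted survival-analysis workflow for
case-cohort studies of incident type 2 diabetes and incident coronary
events, together with the incremental-prediction metrics used to judge
whether a panel of inflammation-related serum biomarkers improves 10-year
risk discrimination over basic and cardiometabolic risk-factor models.
Because no individual-level data of this kind are publicly deposited, the
package also ships a synthetic-cohort generator whose statistical
structure matches the assumptions of the estimators, so that every stage
can be validated end to end against known truth.

## The case-cohort design and weighting

A full cohort of `N` subjects is stratified by survey (S1–S3) and sex.
The case-cohort sample consists of a stratified simple random subcohort —
`round(alpha_s * N_s)` subjects drawn without replacement in each stratum
`s` with sampling fraction `alpha_s` — plus **all** incident cases for the
endpoint under study. One subcohort serves both endpoints (drawn from the
design seed alone); endpoint-specific prevalent-condition subjects
(prevalent diabetes, prevalent myocardial infarction) are excluded from
the endpoint's analysis view afterwards.

Two hazard-estimation weighting schemes are implemented through one
counting-process row representation (entry, stop, status, weight):

* **Prentice** (default): subcohort members are at risk over their whole
  follow-up with weight 1; cases outside the subcohort enter the risk set
  only at `t_i - 1e-8` years, i.e. they contribute to no risk set but
  their own. This is the standard pseudo-likelihood for case-cohort
  hazard estimation.
* **Barlow**: subcohort non-cases are weighted `1/alpha_s`; subcohort
  cases are split into a pre-event segment with weight `1/alpha_s` and an
  event segment with weight 1; outside cases contribute their event only.

With `alpha_s = 1` both schemes reduce exactly to an ordinary Cox model on
the full cohort (the census degeneracy used in the oracle-equivalence
tests). Descriptive statistics always use the pure design weights
(`1/alpha_s` on the subcohort, 1 on outside cases), with a stratified
with-replacement linearization SE (the finite-population correction is
ignored). Variables summarized on the log scale are reported as geometric
means with antilogs of the SE of the log-mean.

## Weighted Cox model

The coefficient vector maximizes the weighted log partial likelihood

    l_w(beta) = sum_events w_i [ x_i'beta - log sum_{j in R(t_i)} w_j exp(x_j'beta) ]

with Breslow handling of ties. Newton–Raphson with step halving is run to
`max |score| < 1e-8` or relative log-likelihood change `< 1e-10` (at most
100 steps); a coefficient escaping beyond ±50 raises a
monotone-likelihood error. Risk-set sums are accumulated as suffix sums
over entry/exit indices rather than forward difference arrays — with
heavy-tailed covariates a subject with an enormous relative hazard who
fails early would otherwise destroy the floating-point precision of late
risk sets.

The variance is the robust sandwich `I^-1 (sum_i g_i g_i') I^-1` with
per-subject aggregated weighted score residuals `g_i`, as required for
validity under case-cohort weighting; Wald tests and 95% CIs
(`exp(beta ± 1.96 se)`) use it throughout, with p < 0.05 flagged
significant.

Continuous covariates are centered internally on the design-weighted
subcohort; biomarkers flagged for z-transformation are standardized by
the weighted subcohort mean and SD (weighted variance with `sum(w) - 1`
in the denominator, reducing to the ordinary n−1 sample convention at a
census), so hazard ratios are per 1 SD of concentration. The moments are
stored in the fit and re-estimated inside every bootstrap replicate, so
standardization uncertainty propagates into intervals.

**Pseudo-AIC.** `aic = -2 l_w + 2k` on the weighted likelihood is not a
true AIC; it is used strictly comparatively between models fitted on the
same sample, with `|delta AIC| > 10` flagged as an essential difference.

**Absolute risk.** 10-year risks are `1 - exp(-H0(tau) exp(x'beta))` with
the Breslow baseline `H0(t) = sum_{t_i <= t} w_i d_i / sum_{R(t_i)} w_j
exp(x_j'beta)`. Regardless of the fitting scheme, `H0` is computed with
inverse-sampling-fraction weights in the risk sets (the Barlow row
representation, evaluated at the fitted beta): under Prentice fitting the
unweighted subcohort risk sets would overstate `H0` by roughly
`1/alpha_s`, which leaves the AUC (rank-invariant) untouched but biases
IDI and NRI. This is the package's main deliberate design choice and is
covered by the design-consistency tests (case-cohort vs full-cohort
estimates) and a calibration-in-the-large check against the weighted
Kaplan–Meier 10-year incidence.

## Discrimination measures at a fixed horizon

All four measures classify subjects by tau-horizon status (default
tau = 10 years): cases have an event by tau, controls are event-free past
tau. Censoring before tau is handled by inverse-probability-of-censoring
weights (IPCW): with `G` the weighted Kaplan–Meier estimator of the
censoring distribution, cases receive `1/G(T-)`, controls `1/G(tau)`, and
subjects censored before tau contribute zero weight (no imputation). The
comparison weight multiplies this IPCW factor by a design factor: cases 1
(complete ascertainment), event-free subcohort members `1/alpha_s`,
event-free subjects outside the subcohort 0 (the subcohort already
represents the event-free population); a `uniform` design mode is exposed
for full-cohort evaluation. The source study describes its
censoring adjustment only as a modified Kaplan–Meier method by citation;
IPCW pairwise weighting is the implementation chosen here, with the
weighted Kaplan–Meier estimator exposed separately so a KM-imputation
variant could be added — under independent censoring the two agree
asymptotically. This is the largest methodological gap the estimators had
to fill.

* **AUC(tau)**: weighted probability that a case outranks a control in
  predicted risk, ties counting 1/2; computed by an O(n log n) rank sweep
  that equals the O(n^2) pairwise definition to machine precision (tested
  at 1e-12).
* **delta AUC**: difference between two models on identical subjects and
  weights.
* **IDI**: difference of discrimination slopes (weighted mean predicted
  risk in cases minus controls).
* **NRI**: net reclassification across risk categories with cut points
  3%/8%/15% by default and 2%/5%/10%, 5%/10%/20% as sensitivity grids.
  Intervals are right-closed (a risk of exactly 3.0% falls in the lowest
  category, matching the printed category labels). 4×4 weighted
  reclassification tables are returned per case status.

## Bootstrap inference

Percentile CIs (default 95%, B = 999 in the full configuration; smaller B
in tests and the acceptance script) resample subjects with replacement
independently within each (case status × survey × sex stratum) cell,
preserving cell sizes — the minimal scheme consistent with the design:
case ascertainment and stratified subcohort sampling are both respected.
Design weights, z-transform moments and all model fits are recomputed on
every replicate. CI endpoints are empirical quantiles of the replicate
values under the type-7 rule (no normal approximation); with `(B-1) *
alpha/2` integral they are exact replicate order statistics. Replicates
on which a fit fails to converge are dropped and counted, with an error
if more than 5% fail.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes:

* **Strata and demographics**: 3 surveys, ~50% male, age uniform on
  25–74.
* **Biomarkers**: 13 mutually correlated log-normal concentrations
  (Cholesky of a configurable 13×13 log-scale correlation matrix; the
  default has acute-phase and chemokine blocks at rho 0.30–0.35 and
  adiponectin anti-correlated with leptin and CRP — a free parameter, as
  no joint distribution is published). Adiposity-linked markers (leptin,
  CRP, adiponectin, sE-selectin, IL-6) mix in standardized BMI on the log
  scale with the marginal log-SD preserved; this coupling is what makes
  the panel's incremental value over the cardiometabolic model smaller
  than over the basic model, as observed in real cohorts.
* **Covariates**: BMI, systolic blood pressure, total/HDL-cholesterol
  ratio (normal); smoking, alcohol, physical activity, parental history,
  prevalent-condition flags (categorical with fixed level probabilities).
* **Event times**: Weibull baseline hazard times `exp(lp)` — exactly
  proportional hazards — with `lp` built from configurable standardized
  log-HRs (analytic moments, so the configured effects are the exact
  data-generating truth). Default effects span HR 0.5–1.4 per SD for
  biomarkers (adiponectin protective), with the basic-model signal (age,
  sex) deliberately stronger for coronary events than for diabetes. A
  shared log-normal frailty (SD 0.3, correlation 0.5) links the two
  endpoints, since the two case sets overlap in one population but no
  joint model is published.
* **Incidence calibration**: the Weibull scale is solved at simulation
  time so the 10-year cumulative incidence matches the configured target
  (10% diabetes, 7% coronary) given the realized linear predictors.
* **Censoring**: administrative horizon 18.2 years minus a uniform entry
  stagger over 10 years. No dropout process, left truncation, assay error
  or competing risks are modeled; fasting/nonfasting variation is out of
  scope.

Passing tests on these cohorts demonstrate internal statistical validity
(estimator consistency, CI calibration, design invariance) under
correctly specified proportional hazards with log-normal markers; they do
not certify behavior under model misspecification, informative censoring
or measurement error, which real cohort data would add.

## Problem sizes and numerical choices

Simulation-based tests use cohort sizes the properties were stated at
(n = 20,000 with 200 replicates for parameter recovery and design
consistency) and smaller cohorts (n = 1,500–6,000) where a property does
not depend on scale; the bootstrap coverage study uses 150 outer
replicates at B = 299 and the null-biomarker calibration study 100
replicates at B = 99, sizes chosen to keep the full suite in the
ten-minute range on one CPU. The acceptance script simulates n = 10,000
with sampling fraction 0.1 and B = 99 panel bootstraps. All randomness
flows from one master seed through named substreams (simulation, design,
bootstrap); reruns are byte-identical.

Degenerate inputs are rejected rather than repaired: non-positive-definite
correlation matrices (reported with the offending eigenvalue), constant
covariates, zero-SD biomarkers, fewer than 2 events, sampling fractions
with `alpha_s * N_s < 1`, horizons beyond the censoring support (with a
suggested earlier tau), non-finite statistics on the original bootstrap
sample.

## Known limitations

* The Prentice pseudo-likelihood sandwich variance ignores the
  finite-population correction of subcohort sampling; empirical coverage
  (92–97% band) is verified by simulation rather than derived.
* The pseudo-AIC has no information-theoretic interpretation under
  weighting; only differences on one sample are reported.
* Category-free (continuous) NRI, time-dependent covariates and
  competing-risk cumulative incidence are not implemented.
* The per-biomarker bootstrap CIs are expensive (two model refits per
  replicate per comparison); the pipeline therefore defaults to
  bootstrapping the panel-level comparisons only (`bootstrap_scope =
  "panel"`), with `"all"` available.
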