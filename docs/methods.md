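# Methods

## Structural and covariate model

Drug disposition follows a two-compartment model with zero-order (constant
rate) infusion input and first-order elimination, parameterized by clearance
CL (L/h), central volume Vc (L), intercompartmental clearance Q (L/h) and
peripheral volume Vp (L).  Concentrations are the central-compartment amount
divided by Vc.  The linear system is solved analytically: the 2×2 propagator
`exp(M·dt)` and the constant-input integral are evaluated from the spectral
decomposition of the system matrix, with a series limit when the two hybrid
rate constants coincide to within a relative tolerance of 1e-10 and when an
eigenvalue vanishes (no elimination).  The same code path therefore covers
the one-compartment reduction (Q → 0) and the mass-balance case (CL → 0)
used by the tests, and the solution is exact up to floating-point error —
the test suite checks it against adaptive ODE integration at a relative
error below 1e-6.

Covariates enter the typical values as

    CL = TVCL · (WT/WTref)^0.75 · MAT(PMA) · (SCrref/SCr)^θ_SCr
    Q  = TVQ  · (WT/WTref)^0.75
    Vc = TVVc · (WT/WTref)
    Vp = TVVp · (WT/WTref)

with `MAT(PMA) = PMA^H / (PMA^H + Mat50^H)`, the Hill (sigmoid Emax)
maturation function of postmenstrual age in days; `MAT(Mat50) = 1/2`
exactly.  Allometric exponents are fixed at 0.75 (clearances) and 1
(volumes).  Linear, exponential and first-order (asymptotic exponential)
maturation functions are available for model-comparison experiments only.

Reference values are `WTref = 1 kg` and `SCrref = 42 μmol/L` (the cohort
median serum creatinine).  These normalizations are configuration, not code:
all reference values live in `PopulationParameters`.  With this choice the
defaults give a typical 1.68-kg, PMA-236-d infant CL = 0.161 L/h
(0.096 L/h/kg) and place 14 mg/kg q8h at AUC24 ≈ 437 mg·h/L — mid-window,
which is where standard NICU dosing is designed to sit.

Random effects are log-normal on CL only: a between-subject effect
(variance ω²_BSV, CV 12.3%) and a between-occasion effect per treatment
episode (ω²_BOV, CV 13.3%); CV and ω² are related by CV = sqrt(exp(ω²)−1).
Residual error is combined proportional–additive,
`sd(f) = sqrt((σ_prop·f)² + σ_add²)` with σ_prop = 0.168 and
σ_add = 1.76 mg/L.  Volume variability is a deliberate extension point that
is off by default: the published variability terms concern CL alone.

## Likelihood and estimation

**Individual (MAP) estimation.**  For a subject with etas η (BSV plus one
BOV per observed occasion) the −2 log posterior is, up to constants,

    Σ_quantified [ ((y−f)/sd)² + 2·ln sd ]  −  2 Σ_BLQ ln Φ((LLOQ−f)/sd)
      + η'Ω⁻¹η

with sd evaluated at the individual prediction (estimation *with
interaction*) and BLQ records entering only through the censored-normal (M3)
term, computed with `log_ndtr` for numerical safety.  The mode is found by
BFGS from zero with up to three jittered restarts; the posterior covariance
is the Laplace approximation, twice the inverse of the central-difference
Hessian (step 1e-4), repaired to the nearest positive-semidefinite matrix if
finite-difference noise produces a negative eigenvalue.  Because the
residual SD depends on the prediction, the posterior mode is *not* exactly
zero even for data simulated at zero etas; the stationarity test therefore
uses an additive-only error model where the property is exact.

**Population (NLME) estimation** maximizes the Laplace-approximated marginal
likelihood with interaction — for this model class it coincides with the
classical first-order-conditional objective to within optimizer tolerance
and extends cleanly to the M3 terms.  Internally each subject's effects are
reparameterized to occasion sums `s_k = η_BSV + η_BOV,k`, an exact linear
reparameterization with prior covariance `ω²_BSV·J + ω²_BOV·I` (inverse and
determinant by Sherman–Morrison), so the inner problem for a single-course
subject is one-dimensional and solved by a safeguarded Newton iteration
(tolerance 1e-9) warm-started across outer iterations; multi-occasion
subjects use BFGS.  Fixed effects, variances and sigmas are estimated on the
log scale (the natural scale for strictly positive parameters); outer
optimization is L-BFGS-B with central-difference gradients (step 1e-4, outer
tolerance 1e-6).  The reported OFV follows the usual convention of dropping
the n·ln 2π constant.  Standard errors come from the outer
central-difference Hessian (step 5e-4); confidence intervals are
`estimate · exp(±z·SE)` on the natural scale; the condition number is the
eigenvalue ratio of the correlation matrix of the estimates (reference
limit 1000); shrinkage is `1 − SD(EBE)/ω`, reported per effect and pooled.
The subject-resampling bootstrap refits resampled cohorts and reports means
and percentile 90% CIs, dropping and counting non-converging replicates.

CWRES are the FOCE-linearized conditional weighted residuals: the model is
linearized in η around the MAP mode, the marginal covariance is
`G Ω G' + diag(sd²)` with sd at the individual predictions, and residuals
are whitened with its Cholesky factor.  BLQ records are excluded.

## Dose individualization

The exposure target is AUC24/MIC in 400–600 h (MIC 1 mg/L by default).  For
linear PK, AUC24 = daily dose / CL exactly, so with a normal distribution
for the log-CL multiplier the PTA of a regimen has a closed form (difference
of two normal CDFs); this is the default evaluation, and a Monte-Carlo path
with common random numbers across the grid exists for distributions without
it (the two agree within Monte-Carlo error by construction, which the tests
verify).  PTA is computed on AUC — residual assay error is excluded —
because the target is exposure, not measurement.

Optimization is exhaustive over a dose grid of 5–30 mg/kg in 0.5 mg/kg
steps (the range observed in the development cohort) and intervals
{6, 8, 12, 18, 24, 36, 48} h, 1-h infusions, all configurable.  Ties within
1e-3 are broken toward the lowest total daily dose and then the longest
interval, minimizing exposure and handling burden; for a point-mass CL this
rule selects the *cheapest* in-window dose rather than the window midpoint,
while for any realistically wide CL distribution the optimum tracks the
geometric midpoint sqrt(400·600) ≈ 490 h.

The empirical (pre-TDM) approach optimizes under the population prior
(BSV + BOV variance).  The Bayesian approach optimizes under the subject's
MAP posterior for the *continuing* occasion — dose adjustment happens within
the ongoing treatment episode, so the current occasion's BOV effect (which
the data inform) applies; a `'new'`-occasion horizon that resets BOV to its
prior is also available.  The legacy comparator scales the dose by
`8.5 / steady-state trough` (linear PK), snapped to the dose grid with the
interval unchanged; a trough at or below the LLOQ caps the scaling at the
policy maximum.

**Comparing approaches on a synthetic cohort** (`evaluate_approaches`): each
approach picks its regimen by its own rule, and the regimen's achieved PTA
is evaluated under a common per-subject measure.  The default measure is the
subject's MAP posterior — the quantity a model-based TDM service can
actually compute, and the one the Bayesian approach maximizes; a `'truth'`
mode evaluating a 0/1 in-window indicator at the simulated true CL is also
provided.  The trough fed to the legacy rule is, by default, the
model-estimated steady-state trough at the subject's MAP point estimate
(`trough_source='predicted'`); feeding a simulated noisy trough measurement
(`'observed'`) is available and markedly degrades that approach, since a
single trough at 2–12 mg/L carries 20–60% relative assay/residual error.

Two structural findings from this engine are worth recording.  First, with
one trough + one peak sample and the published variance structure, a
subject whose samples happen to be uninformative (e.g. a censored trough)
retains essentially the prior uncertainty sd ≈ 0.18 on log-CL, which caps
the attainable window probability at 2Φ(ln(600/400)/(2·0.18)) − 1 ≈ 0.74;
the minimum per-subject Bayesian PTA on a 50-subject cohort therefore
fluctuates around 73–78% across seeds.  Second, under this model a
steady-state trough of 8.5 mg/L corresponds to AUC24 ≈ 320–380 mg·h/L for
q8–q12 dosing (the trough-to-AUC ratio is 35–45 at these intervals), and
the 30 mg/kg per-dose cap prevents long-interval subjects from scaling
higher, so the legacy approach concentrates exposure just *below* the
400–600 window and its median per-subject PTA on the synthetic cohort is
≈15–25% — uniformly mediocre, consistent with the qualitative conclusion
that trough targeting is outperformed by model-based dosing, though not
with a literal 50% median.

## Synthetic cohorts

The generator draws covariates from families moment-matched to the
published cohort summaries (median and IQR), clipped to the published
ranges: truncated normal for gestational age (30.1 ± 6.9 wk, 24.1–41.3) and
dose per kg (14 ± 3 mg/kg, 5–31), truncated log-normal for postnatal age at
first dose (17 ± 14 d, 7–114), birth weight (1.32 ± 0.89 kg, 0.44–4.14) and
SCr (42 ± 34 μmol/L; lower clip 8 μmol/L so the SCr-LLOQ rule is
exercised).  For a log-normal with median m and IQR i the log-scale SD is
`asinh(i/2m)/z₀.₇₅` in closed form.  Gestational age and birth weight share
a Gaussian copula with correlation 0.6 (documented assumption; the true
correlation structure is unknown).  Weight grows linearly at 1.5 ± 0.5%/day;
SCr drifts down 1%/day, reflecting postnatal renal maturation.

Dosing intervals follow PMA/PNA bands after standard neonatal references
(PMA < 30 wk: q24/q18; 30–37 wk: q18/q12; 37–45 wk: q12/q8; ≥ 45 wk: q6 —
the shorter interval after postnatal day 14), with 6–10 doses per course and
one treatment occasion.  The default TDM design mirrors the guideline: one
trough 0.1 h before the fourth dose and one peak at the end of its infusion;
richer designs (e.g. the four-sample design used for parameter recovery)
are configured per run.  Observations are simulated at the subject's
recorded true etas plus combined residual noise and censored at 1 mg/L.

What the generator does *not* emulate: missing and duplicated EHR records,
multi-episode courses, assay-LLOQ heterogeneity across laboratories, site
and sex effects, informative sampling (sicker infants sampled more), or
covariate measurement error.  Passing tests therefore demonstrate internal
consistency of the method chain under the stated generating model, not
performance on real EHR data.

## Problem sizes and numerical choices

* Approach comparison: 50 subjects, closed-form PTA over a 51 × 7 grid
  (seconds).
* Parameter recovery: 100 subjects × 4 samples; free parameters TVCL, Hill,
  Mat50, θ_SCr, TVVc, ω²_BSV, σ_prop, σ_add; TVQ, TVVp fixed (sparse
  trough/peak data carry little information on peripheral distribution) and
  ω²_BOV fixed (a single-course design cannot separate BSV from BOV).  One
  fit takes about a minute; two independent replicates feed the log-TVCL
  bias check.  The Hill coefficient is the least precisely determined of the
  four (its published 90% CI spans roughly ±35%), so its recovery error at
  this cohort size is expected to approach the 20% band.
* pcVPC: quantile bins on time-after-dose (default 8), bins under 3
  observations merged leftward; 95% CIs from replicate-wise percentiles;
  per-subject RNG streams keyed by (seed, subject id) make the result
  invariant to cohort ordering.  BLQ records are excluded from the
  continuous percentiles and compared as per-bin censored fractions; where
  plotted, BLQ values display at LLOQ/2 = 0.5 mg/L.
* Bootstrap coverage checks run deliberately reduced (TVCL free, 20–30
  resamples) — they validate the machinery, not production CIs; production
  use is `bootstrap(..., n=1000)`.
* The variance-explained summary is a documented reconstruction:
  Var(log typical CL with a covariate subset active, others at reference) /
  [Var(log typical CL, all active) + ω²_BSV + ω²_BOV] across subjects at
  first dose.  No standardized published definition exists for this
  quantity, so comparisons against published percentages are qualitative.
* Occasion assignment uses an inclusive 7-day inter-dose gap threshold
  (mirroring the 7-day observation window); "during infusion" is the open
  interval, so an end-of-infusion sample is a peak and is retained;
  equidistant SCr imputation ties take the earlier value (conservative
  toward the pre-dose renal state).

## Known limitations

* The Laplace/FOCE-I equivalence holds for this model class but is not a
  re-implementation of any proprietary estimator; OFV values are comparable
  within this package only.
* MAP posterior covariances come from finite differences; for nearly
  uninformative subjects the Laplace variance can slightly exceed the prior
  variance (the censored likelihood is not globally log-concave).
* The dosing engine treats covariates as frozen at their latest values over
  the prediction horizon; real infants grow and their SCr falls, so
  long-horizon steady-state summaries drift.
* No saturable elimination, no covariates beyond WT/PMA/SCr, no
  MIC-distribution (CFR) analysis, and no AKI outcome modelling.
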