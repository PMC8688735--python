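# Methods

This note documents the models, conventions, numerical choices and
known limitations of `dqtaper`. It is written for users who want to
know exactly what each pipeline stage computes and what the synthetic
cohorts do and do not establish about real data.

## Exposure: the dose quotient

TNF-inhibitor exposure is standardized as the dose quotient

    DQ = (actual dose / standard dose)
         × (standard dosing interval / actual dosing interval) × 100,

so DQ 100 is the full label regimen, DQ 50 is half exposure (for
etanercept 25 mg twice weekly, this is 25 mg once weekly), and DQ 0 is
withdrawal. DQ is invariant to scaling dose and interval by the same
factor and is not capped at 100, so escalation remains representable.
The default registry (etanercept 25 mg / 3.5 d, adalimumab 40 mg / 14 d,
golimumab 50 mg / 28 d, infliximab 5 mg-per-kg / 56 d) reflects standard
label regimens and can be overridden by a YAML file, since full-dose
conventions vary between clinics.

DQ is defined at the canonical visit grid only (months 0, 3, 6, 9, 12,
18, 24); mid-quarter dose changes are out of scope because interval
averages are formed from endpoint values. The interval-average DQ is
the endpoint mean for the four 3-month intervals and
`(DQ12 + 2·DQ18 + DQ24)/4` for the 12–24-month interval — the mean of
its two half-interval means, so the weighting is consistent with
inserting the midpoint visit explicitly.

## Interval structure and status classification

Follow-up is partitioned into five intervals (0–3, 3–6, 6–9, 9–12,
12–24 months), five records per patient. Response/relapse status is a
function of ASDAS-CRP at the interval endpoints: *response* iff the
endpoint value is below 2.1 (covering both "remained in remission/low
disease activity" and "fell from high to low"), *relapse* otherwise
(rose to, or stayed at, high disease activity). Evaluating "within the
interval" at endpoints is forced by the data model: disease activity is
measured at grid visits only, so no intra-interval trajectory exists.
The 1.3 (remission) and 2.1 (low-disease-activity) thresholds are
exposed as named constants.

Missing interior MRI (months 3, 6, 18 in practice) is imputed by linear
interpolation between the nearest measured neighbours; months 0, 12 and
24 must be measured, and leading/trailing gaps are an error rather than
an extrapolation. ASDAS-CRP gaps are a validation error, not an
imputation target, because status must not silently rest on imputed
disease activity. Per-interval MRI deltas are end-minus-start of the
completed series; bone-marrow edema counts as "increased" only for a
strictly positive SPARCC change (no change is not an increase).

## Stabilized IPTW for a continuous exposure

The exposure model is Gaussian: average DQ is regressed on a covariate
set by least squares and the conditional density of the observed
exposure is evaluated under the fitted mean with the maximum-likelihood
(n-denominator) residual SD. The stabilized weight is the density
ratio

    SW = f(avg DQ | V) / f(avg DQ | V, ASDAS-CRP at interval start),

with V the baseline covariates (sex, age, diagnosis, disease duration,
smoking, HLA-B27; reference levels female, nr-axSpA, non-smoker,
HLA-B27-negative). Weights are pointwise per interval by default; a
cumulative-product variant over each patient's interval history is
available behind a flag for sensitivity analysis, since either
convention is defensible for interval-structured data. Weights are
untruncated by default; percentile winsorization is available as
standard hygiene. Diagnostics (mean, min, max, Kish effective sample
size) are always reported — a mean far from 1 signals a misspecified
numerator or denominator.

## Weighted GEE

Dose effects are estimated by generalized estimating equations with an
identity link and Gaussian working variance, clustered by patient, for
all five outcomes: ΔSPARCC, Δfat metaplasia, Δerosion, Δbackfill and
the 0/1 relapse indicator (a linear probability model, so its slope
reads as change in relapse probability per DQ unit). The regression is
deliberately univariate in average DQ; covariate adjustment happens
only through the weights, keeping the weighted and unweighted fits
directly comparable.

Under the default independence working correlation the point estimate
is exactly weighted least squares; the exchangeable option estimates a
common within-cluster correlation from Pearson residuals and iterates
to convergence (tolerance 1e-8 on the coefficients, 50 iterations
maximum, failure raised with the iteration trace). Variance is always
the cluster-robust sandwich, which reduces to HC0 with one observation
per cluster; confidence intervals are Wald (±1.96·SE) and p-values
two-sided normal, with no small-sample correction. Estimates are
invariant to cluster ordering and to rescaling all weights by a
constant.

## ROC analysis and cut-offs

Two discrimination questions are asked of the interval records: does
higher average DQ predict treatment response, and does it predict a
stable SPARCC score? The positive class is the favourable state in
both, so reported cut-offs read as minimum maintenance doses, and the
sensitivity/specificity pair at the cut-off is always labelled
explicitly rather than printed as a bare ordered pair. The weighted
ROC uses weighted class totals (sensitivity at threshold c is the
weighted fraction of positives with score ≥ c); with unit weights it is
bit-identical to the unweighted computation because there is one code
path. The AUC is the trapezoidal area, which equals the weighted
pairwise concordance with ties counted one half. Cut-offs maximize
Youden's J, with exact ties broken toward the higher threshold (a
tolerance of 1e-12 keeps floating-point noise from breaking ties);
closest-to-top-left is available as an alternative. The "GEE" versus
"GEE+IPTW" ROC variants are unit versus stabilized weights on the same
records. No AUC confidence interval is computed.

## Survival and descriptive statistics

Relapse timing is interval-grained: the event time is the end month of
the first relapse interval (3, 6, 9, 12 or 24) and never-relapsed
patients are censored at 24 months. Events anywhere in the final
interval are therefore dated to month 24 — the grid cannot resolve
finer timing, which coarsens medians relative to visit-level dating.
Kaplan-Meier estimation, the Brookmeyer-Crowley (log-log) median CI and
the log-rank test are delegated to lifelines; Greenwood standard errors
are computed alongside from the event table. Group comparisons use
Mann-Whitney U (asymptotic, tie- and continuity-corrected; the default
for continuous variables, which are summarized as median [IQR]) or
Welch's t (mean ± SE), and chi-square with Yates correction for 2×2
tables unless any expected cell is below 5, in which case Fisher's
exact test is used. A 24-month relapse rate is by construction the
complement of the never-relapsed fraction.

## Synthetic cohorts

The generator produces the structure the analysis assumes, with known
coefficients:

* **Arms and dosing.** Exact arm sizes (63 tapering / 45 withdrawal at
  the 108-patient default), full dose at month 0 for everyone, taper
  tracks of 66.7/35/16.7% or 50/25/12.5% starting at month 3 or 6 with
  three-month phases, withdrawal reaching DQ 0 by month 12.
* **Time-varying confounding.** Under the default `track-hold` policy a
  planned reduction is held with probability `confounding_strength`
  (default 0.7) when ASDAS-CRP at the decision visit is at or above the
  remission threshold 1.3 — clinicians taper more slowly when the
  patient is not in deep remission. Under the `continuous` policy the
  next DQ adds `confounding_strength` DQ units per ASDAS unit above 2.0
  plus Gaussian noise (SD 8 by default); this is the regime in which
  the weighting stage's Gaussian treatment model is correctly
  specified. The real dose-decision process is unobserved; both rules
  are explicit assumptions and fully parameterized.
* **Outcomes.** Each interval's MRI score change is
  `intercept + slope·avgDQ + confounder_effect·(ASDAS_start − 2) +
  patient effect + noise`, with default slopes −0.096 (SPARCC), 0
  (fat), −0.010 (erosion), −0.0034 (backfill) per DQ unit — values of
  the magnitude the analysis is meant to detect. Intercepts
  (4.0/1.8/2.0/1.0) are set so expected trajectories flatten near the
  instrument floors instead of crossing them, keeping bound clipping
  below 5% of generated cells at the defaults (the realized fraction is
  recorded in the ground-truth file). Cluster SD 0.4, per-outcome noise
  SD 0.5–1.2.
* **Relapse.** The interval relapse indicator is Bernoulli with
  probability `clip(1.15 − 0.034·avgDQ + 0.08·(ASDAS_start − 2.1), 0, 1)`,
  and the ASDAS-CRP endpoint is then drawn on the matching side of 2.1,
  so endpoint classification reproduces the drawn indicator exactly and
  relapse rates, survival curves and status-based ROC stay internally
  consistent. With these defaults the tapering arm relapses far less
  and later than the withdrawal arm (median time to relapse 24 versus
  12 months), qualitatively matching a tapering-versus-withdrawal
  cohort, though arm-level rates are emergent rather than calibrated.
* **Missingness.** MRI at months 3, 6 and 18 is missing completely at
  random with probability 0.5 each; months 0, 9, 12 and 24 are always
  scanned.

Two presets matter for validation. The *paper-shaped* preset is the
default configuration above. The *recovery* preset
(`recovery_config`) uses a single tapering arm, the continuous dose
policy, no MRI missingness and no bound clipping, so the configured
slopes are exactly the estimands; it is the basis of the n=400 recovery
run and the 200-seed coverage study (n=150 per seed, confounding off).
A third harness (`simulate_interval_table`) generates interval records
directly with an exactly Gaussian-linear exposure model; it isolates
the stabilized-weighting properties (mean weight 1, covariate balance,
bias reduction in 100 confounded replicates) from any dose-policy
misspecification.

What passing these simulations shows — and does not. They establish
that each engine computes what it claims (oracle equivalences), that
the weighting corrects confounding when its model is right, and that
the end-to-end pipeline recovers known interval-level linear effects.
They do not establish robustness to misspecified exposure densities,
informative MRI missingness, reader noise, mid-quarter dose changes or
treatment switching, none of which the generator emulates.

## Numerical choices and degenerate inputs

* Residual SD in both weight densities is the ML (n-denominator)
  estimate; the choice is fixed and documented because the density
  ratio is insensitive to it only asymptotically.
* A numerically zero denominator density raises a weight-overflow error
  naming the record rather than returning an infinite weight.
* Rank-deficient treatment designs raise an error naming the collinear
  columns.
* The sandwich variance is refused for a single cluster.
* ROC analysis refuses single-class labels; all-tied scores yield AUC
  0.5.
* Validation errors always name the offending table, patient and field.
* Problem sizes of the validation studies (400 patients for the single
  recovery run; 200 × 150 patients for coverage; 100 × 150 for the
  confounded comparison) were chosen as the smallest sizes at which
  sampling noise does not dominate the properties being demonstrated.

## Known limitations

* Relapse uses an identity-link linear probability model, not logit;
  fitted probabilities are not constrained to [0, 1].
* Pointwise (not cumulative) stabilized weights are the default; the
  cumulative product is available but its finite-sample behaviour on
  five-interval histories is more volatile.
* Event times are interval-grained; a cohort with visit-level relapse
  dates would justify finer survival analysis than this data model can
  express.
* The descriptive test menu switches between parametric and
  non-parametric variants by convention (expected cell counts,
  explicit user choice), not by formal model selection.
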