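# dqtaper

Dose-quotient tapering analysis for TNF-inhibitor (TNFi) reduction in
axial spondyloarthritis (axSpA).

Many axSpA patients who respond to a TNFi must later reduce or stop it
(cost, infection risk, injection burden). The clinical question is how
much drug can be withdrawn before relapse and sacroiliac-joint (SIJ)
damage progression outweigh the savings. `dqtaper` implements, as a
tested and reusable pipeline, the observational analysis used to answer
it in two-year tapering-versus-withdrawal cohorts — and a synthetic
cohort generator with known ground truth so every stage can be
validated without patient data. It is aimed at biostatisticians and
rheumatology researchers analysing longitudinal dose-reduction cohorts.

## The analysis

**Exposure.** Any TNFi regimen is standardized to a *dose quotient*

```
DQ = (actual dose / standard dose) × (standard interval / actual interval) × 100
```

(DQ 100 = full regimen; etanercept 25 mg weekly against a standard of
25 mg twice weekly is DQ 50; withdrawal is DQ 0). Two years of
follow-up are split into five intervals (0–3, 3–6, 6–9, 9–12, 12–24
months; 5 records per patient), each carrying its average DQ — the
endpoint mean, with (1,2,1)/4 weighting for the final interval.

**Outcomes.** Per-interval changes in SIJ MRI scores (SPARCC
bone-marrow edema 0–72; SSS fat metaplasia, erosion, backfill) after
linear interpolation of missing interior scans, and a response/relapse
status from ASDAS-CRP at the interval endpoints (relapse iff the
endpoint is ≥ 2.1).

**Causal adjustment.** ASDAS-CRP at interval start is a time-varying
confounder: it influences both the next dose decision and the outcome.
Records are reweighted by stabilized
inverse-probability-of-treatment weights for the continuous exposure,

```
SW = f(avgDQ | baseline covariates) / f(avgDQ | baseline covariates, ASDAS_start)
```

with Gaussian conditional densities from linear exposure models
(marginal-structural-model estimation).

**Estimation.** Weighted GEE with identity link, clustered by patient,
cluster-robust sandwich variance: `Δscore = β0 + β1·avgDQ` for each MRI
outcome, and a linear probability model for relapse. Weighted ROC
curves of average DQ against response status and SPARCC stability give
Youden-optimal cut-offs that read as minimum maintenance doses;
Kaplan-Meier curves, Brookmeyer-Crowley median CIs and the log-rank
test summarize time to first relapse.

## Worked example

```
dqtaper run-all --out results --seed 5
```

simulates the default 108-patient cohort (63 tapering / 45 withdrawal),
builds the 540 interval records, fits the weights and all models, and
prints a report. Key excerpts from that exact command:

```
## Effects (GEE slope of average DQ, 95% CI)
  d_sparcc     GEE       beta -0.0741 [-0.0779, -0.0703]  p=0
  d_sparcc     GEE+IPTW  beta -0.0810 [-0.0850, -0.0770]  p=0
  d_fat        GEE+IPTW  beta -0.0009 [-0.0030,  0.0012]  p=0.3859
  d_erosion    GEE+IPTW  beta -0.0111 [-0.0131, -0.0090]  p=1.289e-26
  relapse      GEE+IPTW  beta -0.0089 [-0.0097, -0.0081]  p=9.195e-112

## Discrimination (ROC of average DQ)
  response               GEE+IPTW  AUC 98.6%  cutoff 25.0 (sens 90.8%, spec 95.9%)
  sparcc_not_increased   GEE+IPTW  AUC 96.4%  cutoff 29.2 (sens 91.1%, spec 91.5%)

## Survival (time to first relapse)
  tapering    median not reached (95% CI 24-inf); relapse rate 11.1% at 12 mo, 39.7% at 24 mo
  withdrawal  median 12 months (95% CI 9-12); relapse rate 80.0% at 12 mo, 100.0% at 24 mo
  log-rank chi2 = 73.62, p = 9.47e-18
```

Reading the numbers: each extra DQ unit maintained slows SPARCC
progression by ≈0.08 points per interval and lowers the per-interval
relapse probability by ≈0.9 percentage points (the simulator's true
coefficients are −0.096 and −0.034 before interval clipping); the ROC
cut-offs say that in this cohort keeping the average DQ above ≈25–29
best separates responders from relapsers and stable from worsening
bone-marrow edema; and withdrawal relapses far earlier than tapering.
Fat metaplasia, generated with a null dose effect, is correctly flat.
The simulated AUCs are higher than one should expect in a real cohort:
interval-level outcomes here depend on dose more cleanly than real
disease does.

The generated truth is stored next to the cohort
(`results/cohort/ground_truth.json`), and each stage is also available
as its own subcommand (`dqtaper simulate | dq | intervals | weights |
fit | roc | survival | describe | report`) operating on plain CSV
tables, so any stage can be swapped out or inspected.

As a library:

```python
import dqtaper as dt

cohort, truth = dt.generate_paper_shaped(seed=5)
records = dt.build_interval_table(cohort)          # 540 rows
w = dt.stabilized_weights(records)
fit = dt.fit_gee(records, "d_sparcc", weights=w.weights)
print(fit.slope, fit.slope_ci)                     # -0.081 (-0.085, -0.077)
```

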