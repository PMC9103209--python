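# Methods

## The oncomiR index

For a panel of oncogenic miRNAs with relative expressions
`Abundanceᵢ > 0` (dimensionless, see Quantification) the index is the
weighted sum

    score = Σᵢ cᵢ · Abundanceᵢ ,     cᵢ ≥ 0,

and the probability of CNS involvement is the logistic transform

    P(CNS) = 1 / (1 + exp(X − score)),

with intercept `X`.  `P` is strictly increasing in the score and equals
0.5 exactly at `score = X`, so classification at a threshold on the score
scale and on the probability scale are equivalent.  Eight published
presets ship in `src/oncomir/data/presets.json` (per-subtype panels,
coefficients, and raw + log2 decision thresholds).  The presets publish no
intercept, so probability computation with a preset requires `X`
explicitly; the score and the threshold call never need it.  A sample is
called CNS-involved iff `score ≥ threshold_raw` — the boundary itself is
positive, because the published cut-offs are cut-offs *for* involvement.
(The original discussion also quotes a DLBCL-CSF threshold of 8.2; the
preset uses the tabulated 8.42, and the two differ only in which
operating point is favoured.)

### Coefficient fitting

`fit_coefficients` maximizes the class-probability gap

    J(c, X) = mean{ P(CNS) | CNS-positive } − mean{ P(CNS) | systemic }.

`J` is scale-degenerate: multiplying `(c, X)` by a large constant drives
`P` toward a 0/1 step function and inflates `J` without bound, so the
problem is only well-posed on a box — by default `cᵢ ∈ [0, 10]`,
`X ∈ [−20, 20]`.  Optimization is a deterministic multi-start bounded
quasi-Newton (L-BFGS-B) search with analytic gradients from a seeded set
of 16 starting points; among near-equal optima (within 1e−6) the smallest
coefficient L2 norm wins, for reproducibility.

The fit then sparsifies by **backward elimination**: a miRNA is assigned
coefficient 0 and excluded from the panel when refitting without it costs
less than `drop_tol = 0.02` of the objective.  `J` is a difference of two
sample means of [0, 1] variables, so its sampling noise at cohort scale
(~100 per class) is of order 2/√n ≈ 0.02; in-sample contributions below
that floor are indistinguishable from overfitting, and retaining them
would keep spurious weights on uninformative miRNAs.  The last remaining
miRNA is never eliminated — on uninformative data the objective is near 0
and no coefficient is stable, which the caller can read off `objective`.

### Longitudinal monitoring

`flag_rising_trajectory` raises an alert when some window of `k = 2`
consecutive strictly increasing index values achieves a total rise of
`≥ 1.5×` from the window start.  The defaults reflect the observed
pre-relapse kinetics: the index climbs over the 1–4 months (median ≈ 3)
preceding a clinically detected CNS relapse.

## Quantification

Relative expression is `2^−(Ct_target − Ct_reference)` with miR-let-7a as
the endogenous reference.  Conventions:

- **Duplicates** are averaged on the Ct scale (replicate noise is
  approximately Gaussian in cycles); a replicate range > 1.0 cycle is
  flagged.
- **Undetermined wells are missing**, never a pseudo-Ct of 40 — imputing
  the detection limit would fabricate signal exactly where the assay says
  there is none.  Every missing output value traces to a QC flag.
- **Spike-in QC**: a sample fails when its cel-miR-39 Ct deviates from
  the batch median by > 2.0 cycles (per-compartment batches, minimum 3
  samples).  Failed samples are excluded from equalization denominators
  but kept, flagged, in the table.
- **Equalization** divides by the *mean* relative expression of a
  designated reference group per (miRNA, compartment), making that
  group's mean exactly 1.  The default reference is the non-lymphoma
  control group; the systemic-lymphoma group can be designated instead
  (both conventions appear in the source analyses), via the
  `reference_group` argument.

Equalized values are invariant to global abundance rescaling (shifting
all target Cts by a constant), which the suite checks as a property.

## ROC and threshold selection

The positive call convention is `score ≥ cut-off` throughout.  Candidate
cut-offs are the observed distinct scores plus midpoints between
consecutive distinct scores and ±∞ sentinels — a finite, deterministic
set that is decision-equivalent to every real threshold.  AUC is the
Mann-Whitney concordance probability with ties credited 0.5; trapezoidal
integration of the curve agrees with it to 1e−12 by construction and is
asserted internally on every call.  The operating point minimizes
`(1 − sens)² + (spec − 1)²` on fractional sensitivity/specificity, with
ties broken toward higher Youden index, then higher specificity, then
finite cut-offs.  Reported sensitivity/specificity are percentages; the
Youden index is `sens% + spec% − 100`.

## Group comparisons

Mann-Whitney U uses exact enumeration when both groups have ≤ 8
observations and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections (delegated to scipy).
A pooled-constant sample yields U = n·m/2, p = 1 with a degenerate flag
rather than an error.  Kruskal-Wallis carries the standard tie
correction.  Dunn's post hoc z statistics are computed from mean-rank
differences with the pooled tie-corrected variance; the adjustment
defaults to Bonferroni (Holm and none available) — the adjustment choice
is a package decision, not dictated by the source analyses.  Quartiles
use the Tukey inclusive-hinge rule to match common clinical-stats
software.

## Survival and risk stratification

Kaplan-Meier, log-rank (Mantel-Cox) and Cox proportional-hazards
estimation are delegated to `lifelines`; Cox uses Efron tie handling,
Wald 95% CIs from the observed information, and likelihood-ratio
p-values.  Cumulative incidence of CNS relapse at a horizon (default 48
months) is `1 − KM(t)`, matching the published treatment of death as
censoring; an Aalen-Johansen competing-risk estimate is available behind
`competing_risk=True` for sensitivity analysis and is never larger than
the naive estimate.  OncomiR high/low stratification is `score ≥ cutoff`
with the ROC closest-corner threshold as the default cut-off — the only
threshold rule the source analyses state.  The combined risk model
crosses oncomiR high/low with dichotomized CNS-IPI (high vs
low/intermediate): *both risks* / *one risk* / *no risk* partition the
labeled cohort.

## Synthetic cohorts

The generator emulates the study conditions so that downstream stages
are testable without the (undeposited) patient data:

- **Cohort layout**: 22 controls; DLBCL 72 systemic / 25 CNS-involved;
  MCL 19/15; BL 13/5; B-NHL-NOS 4/9; paired CSF and plasma samples per
  patient.
- **Abundances** are log-normal on the 2^−ΔCt scale: log2 abundance ~
  Normal(base + log2 FC, sd), sd 1.0 log2 units per compartment.
  Log-normality is a modelling assumption (the source analyses plot
  log2-scale medians with IQRs but state no distribution); it keeps Ct
  noise Gaussian in cycle units.  Default fold changes over control:
  CSF 1× systemic / 4× CNS-involved; plasma 2× systemic / 4×
  CNS-involved — i.e. a 4× CSF and 2× plasma CNS-vs-systemic ratio, with
  systemic plasma elevation matching the observed ~2× over controls.
- **Ct synthesis** inverts the 2^−ΔCt relation exactly
  (`Ct_target = Ct_ref − log2 abundance`, reference mean 25 cycles,
  spike-in 20), then adds Gaussian replicate noise (0.25 cycles) to each
  duplicate.  At zero noise the quantification round trip recovers the
  latent fold changes exactly, which the suite asserts.
- **Trajectories**: responders decay linearly (in log2) from the
  CNS-involved level to baseline; refractory series rise monotonically;
  pre-relapse series stay flat and rise from `onset_months` (default 3,
  range 1–4 configurable) before the recorded relapse.
- **Survival**: relapse and death times are exponential with hazard
  `h₀ · exp(β · log2 score)` (defaults h₀ = 0.01/month for relapse,
  0.008 for death, β = 0.8), independent given the score, with
  administrative censoring at 60 months.  A `censor_rate` fraction
  (default 0.2) is censored at enrollment (time 0).  Entry censoring is
  deliberate: suppressing the events of a fixed fraction *during*
  follow-up is informative censoring and measurably attenuates
  hazard-ratio estimates, whereas entry censoring is an independent
  thinning and leaves Cox estimation unbiased.

What the generator does **not** emulate: extraction-chemistry or
hemolysis artifacts, serum coagulation effects, inter-assay batch drift,
correlated miRNA co-regulation, or competing-risk coupling between
relapse and death.  Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generative model, not
clinical performance on real cohorts.

## Problem sizes and numerical choices

The test and acceptance workloads are sized for quick, reproducible
desk-scale runs: 400 random ROC instances up to n = 200 against an O(n²)
oracle; coefficient recovery over 20 seeds at 100 samples per class; Cox
recovery over 50 seeds at n = 400; null calibration on a 500 + 500
no-signal cohort and 1,000 Mann-Whitney replicates.  All randomness
derives from a single seed per run; fixed seeds give byte-identical
synthetic tables and pipeline bundles.  Degenerate inputs (constant
samples, event-free strata, all-undetermined wells) return flagged
neutral results rather than raising, except where an analysis is
genuinely impossible (single-class ROC, empty equalization reference,
constant Cox covariate).

## Known limitations

- The fitted intercept `X` is reported but weakly identified once the
  classes are well separated (the objective plateaus); only the linear
  score and threshold are used downstream.
- The probability-gap objective is not a proper likelihood; no standard
  errors are attached to fitted coefficients.
- `1 − KM` overstates relapse incidence when death competes; the
  Aalen-Johansen flag quantifies the difference.
- Exact Mann-Whitney enumeration is skipped in the presence of ties
  (mid-rank asymptotics are used instead), the standard compromise.
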