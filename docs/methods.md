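# Methods

`crlandmark` implements dynamic prediction of competing first events after
curative rectal-cancer surgery — relapse, cancer death and other-cause
death — through landmarking: the survival model is refitted/re-evaluated on
the subset of patients still event-free at each of several landmark times,
and the per-landmark risk sets are stacked into one "super dataset" with
landmark time as a covariate and patient id as a cluster label.

## Synthetic cohort generator

No public registry ships with the package, so every analysis runs on a
synthetic cohort whose structure mirrors a multicentre surgical registry
(n ≈ 2,400, median follow-up ≈ 6 years).

**Model.** Each patient carries 20 baseline covariates Z (demographics,
comorbidity, operative and pathological features). Conditional on Z, three
latent event times are drawn with cause-specific hazards

    lambda_k(t | Z) = lambda_k0 * exp(beta_k' Z~) * a * t^(a-1),   k = relapse, cancer death, other death

with shape a = 1 by default (constant hazards); Z~ centres/standardizes
continuous covariates internally while the CSV keeps natural units. An
independent exponential censoring time and an administrative cut-off at 15
years compete with the events; the observed record is the first of the
five, giving exactly one event code per patient (semi-competing structure
is deliberately not modelled: first event only).

**Parameterization.** Covariate marginals match the emulated registry's
overall column (61.7% male, median age 66.6, BMI 25.3, 56.5% laparoscopic,
7.8% pM1, ...). The log hazard ratios are the natural logs of the
registry's univariable cause-specific point HRs, set to 0 where the
univariable test was null. Two notes: (i) operative time had a
significant p-value but a printed per-minute HR of 1.00, which carries no
usable magnitude, so its coefficient is 0; (ii) univariable HRs used
jointly overstate total effect sizes — acceptable here because the
generator defines a test bed, not an estimate of the real registry.

**Stage consistency.** pT, pN, pM are mapped from a shared latent severity
score (correlation 0.6) through quantile cuts that preserve their
marginals, and TNM stage is derived deterministically (>III iff pN≥1 or
pM=1), which reproduces its 36% marginal. All other covariates are
independent — the registry reports no joint distribution, and no
dependence beyond stage consistency is imposed.

**Calibration.** Baseline cause rates and the censoring rate were fixed
once by a Monte-Carlo fixed-point routine (`calibrate_rates`, 150k samples
per iteration) so that large-sample event fractions are ≈8% relapse, ≈8%
cancer death, ≈20% other-cause death with median follow-up ≈6 years; the
resulting rates are frozen in `default_cohort_config`.

**What the generator does not emulate:** informative censoring,
time-varying covariates, missing data (an MCAR mask can be applied by the
user but is never generated), centre effects, semi-competing relapse→death
sequences, and any covariate dependence beyond the stage block. Passing
tests therefore certify the estimators and the pipeline mechanics under a
correctly specified, independent-censoring world — not performance on real
registry data.

## Landmarking

Landmark datasets keep patients with time > s (strict: failing exactly at
s is not "at risk after s"). The default fitting grid is yearly landmarks
1..15; tables and profile curves report at 1, 3, 5 years. No prediction
horizon is applied by default (risk sets follow each patient to the end of
observation); a sliding-window `horizon` is available, truncating at s+w
with administrative censoring. Covariates are baseline-only and carried
unchanged.

## Model A — cause-specific Cox landmark supermodel

For one cause, competing events are treated as censoring (cause-specific
convention) and a single Cox model is fitted to the stacked super dataset
with:

- main effects for the covariates (continuous terms standardized, so their
  HRs are per SD; categorical terms expanded against the first sorted
  level),
- a landmark-time main effect scaled to decades,
- optional interactions linear in s, giving HR(s) = exp(beta + gamma*s)
  with delta-method CIs from the robust covariance,
- a sandwich variance clustering score residuals on patient id (a patient
  contributes correlated rows at several landmarks),
- Efron tie handling (lifelines backend).

**Time scale.** Duration is measured on the conditional-survival clock,
t − s (time since the row's landmark), with pooled risk sets across
landmarks. This is a deliberate design choice: on the from-surgery clock
with unbounded risk sets, every patient at risk at time t carries an
identical multiset of landmark copies, so the landmark-time main effect is
identified only through tie patterns and degenerates numerically (we
observed it pinned at 0 or diverging depending on the interaction
structure). On the conditional clock the effect is cleanly identified and
shows the expected attenuation of risk with time already survived. At a
single landmark s = 0 the two clocks coincide, so the supermodel reduces
exactly to a standard cause-specific Cox fit.

**Default interaction set.** The pipeline interacts landmark time with
anastomotic dehiscence, combined multivisceral resection and IMA ligation
level — variables whose at-risk prevalence persists across landmarks.
Distant metastasis (pM) enters as a main effect only: under the
generator's extreme pM hazards (relapse HR 6.9, cancer-death HR 10.6),
pM=1 patients are essentially depleted from late landmark risk sets, so a
pM × s coefficient is identified only by a handful of rows and its
estimate swings wildly between seeds (we observed HR(1y) estimates from 5
to 650 across seeds with the interaction included, against a stable 6–8
without it). Users can still request any interaction set explicitly.

Wald tests use the robust covariance: the "global" p is the joint test of
a variable's main and interaction coefficients, the "interaction" p tests
the interaction alone (reported as NaN when absent). No multiplicity
correction is applied. Rare near-separated fits (extreme metastasis
effects emptying late landmarks) are retried with damped Newton steps
(step sizes 0.25, then 0.1) before an error is raised.

## Model B — competing-risk random survival forest

Authored from scratch (no off-the-shelf RSF handles competing risks):

- **Cluster bootstrap.** Patients are resampled with replacement
  (n_clusters draws); all landmark rows of a drawn patient enter in-bag
  together with multiplicity. OOB patients are those never drawn
  (≈ (1−1/n)^n ≈ 36.8% per tree).
- **Splitting.** At each node, `mtry` variables are drawn without
  replacement; unordered categoricals contribute level-vs-rest indicator
  columns, continuous variables all midpoints between sorted unique
  values. The score is the squared generalized log-rank numerator over
  its hypergeometric variance, computed per cause with cause-k events as
  events and everything else censored; the default composite rule averages
  the three per-cause scores so one forest produces all three CIFs
  (cause-specific forests via `split_cause`). Delayed entry at
  `landmark_s` is honored inside every risk-set count, and landmark time
  itself is an ordinary splitting covariate. For speed the within-node
  risk grid is coarsened to at most `max_grid` (default 32) event times —
  a numerical choice affecting only the split score, never the CIFs; the
  scan itself is numba-compiled.
- **Stopping.** A split must leave ≥ `nodesize` rows in each daughter;
  event-free nodes and nodes with no admissible split become terminals.
- **Terminal estimates.** Each terminal stores the delayed-entry
  Aalen–Johansen CIF of its member rows on exact event times:
  F_k(t) = Σ_{t_i≤t} S(t_i−) d_k(t_i)/Y(t_i) with S the all-cause
  Kaplan–Meier. The IPCW weighting form of the same estimator is
  implemented independently and the two agree to 1e-10 (tested), the
  events-before-censoring tie convention making them algebraically
  identical.
- **Prediction.** A profile is dropped down every tree with landmark_s set
  to s; terminal CIFs are averaged on the pooled training event grid and
  re-anchored at s: F_k(t|T>s) = (F_k(t)−F_k(s))/S(s).
- **OOB error.** For each row, only trees whose bootstrap excluded the
  row's whole cluster contribute; the risk score is the OOB-ensemble
  conditional cause-k CIF mass on (s, tau], tau defaulting to the 90th
  percentile of observed times. The OOB error is 1 − C with the
  concordance rule below.
- **Tuning.** Grid search over mtry × nodesize (ntree fixed at 100)
  minimizing the mean per-cause OOB error, ties broken toward larger
  nodesize then smaller mtry. On the default generator the tuned optimum
  is mtry = 5, nodesize = 30 (OOB error 0.200 vs 0.227 at nodesize 5),
  and those are the pipeline defaults.
- **Minimal depth.** Per tree, the depth of the first split on each
  variable; never-split variables contribute that tree's maximal depth +1;
  the forest averages over trees. As in any RSF, minimal depth favours
  variables with many candidate cutpoints (continuous over rare binaries)
  and is a ranking device, not an effect size.

Determinism: one child RNG stream per tree derived from the config seed;
a fixed seed reproduces the forest, its OOB error and the minimal-depth
table bit-for-bit.

## Evaluation

**Concordance.** Harrell's C adapted to competing risks with the
cause-specific convention: pair (i, j) is comparable when i has a cause-k
event at t_i before the truncation time (90th percentile of follow-up by
default) and j is still under observation at t_i; competing events are
treated as censored at their time. Score ties count 1/2. The forest's
risk score is the conditional cause-k CIF mass up to the truncation
horizon; the Cox score is the linear predictor at the row's landmark.

**Cross-validation.** Grouped five-fold CV on patients (all landmark rows
of a patient share a fold). The report emits the pooled out-of-fold C,
the per-fold values and their mean — the three ways a cross-validated C
can be summarized — to keep that ambiguity explicit.

**Bootstrap CI.** 100 cluster-bootstrap replicates of the evaluation set,
metric recomputed per replicate without refitting, outward-rounded
2.5/97.5 percentiles (at B=2 the interval is exactly (min, max)).
Replicates with an undefined metric are dropped with a warning; >20%
dropped is an error.

## Patient profiles

The "better"/"worse" profiles are manually defined clinical contrasts,
both 65-year-old men. Unquantified anchors are resolved as: prolonged
operative time = 90th percentile, minimal anal-verge distance = observed
minimum, mid-to-high localization = "middle" (the modal level); the worse
profile's Charlson score is the cohort median. Profile curves are the
forest's conditional CIFs at landmarks 1, 3, 5 years, anchored at 0 at
each landmark.

## Problem sizes and numerical choices

Default problem sizes: cohorts of 2,000–2,405 patients (the emulated
registry's size), yearly landmark grids to 15 years for Model A,
reporting grids {1,3,5} for the forest and profiles, ntree = 100. The
test suite uses smaller cohorts per check (600–20,000 depending on what
the check estimates), chosen so each statistical property is tested at a
scale where its expected noise is far below the asserted tolerance.
Tolerances: exact-oracle comparisons at 1e-10..1e-12; parameter recovery
at 3 asymptotic SEs; calibration checks at ±2 percentage points.

## Known limitations

- Strict pointwise dominance of two estimated CIF curves (worse ≥ better
  at every one of thousands of grid times) fails in roughly 1–2 of 10
  seeds by O(1e-3) — single-terminal sampling noise just after the
  landmark anchor — even though the true curves are separated by an order
  of magnitude. The corresponding acceptance test asserts the strict
  property and documents this.
- Minimal depth inherits the usual RSF preference for continuous
  variables; rare strong binaries (e.g. pM1 at 7.8% prevalence, further
  depleted at later landmarks) can rank below weaker continuous effects.
- The Cox supermodel reports per-SD HRs for continuous terms; per-unit
  HRs require dividing the log-HR by the training SD.
- C-index values on synthetic cohorts are not comparable to any real
  registry's values; only the qualitative model ordering is meaningful.
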