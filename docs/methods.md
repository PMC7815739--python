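# Methods

## The dynamic prognostic model

ACLF prognosis is modelled as a 90-day binary outcome. The score combines
three baseline covariates (age; WGO chronic-disease type coded ordinally
1/2/3; alcoholic-etiology indicator), three landmark lab values (TB, Cr in
mg/dL; PTA in %), and one dynamic summary, the SDTs. At a landmark
timepoint t ∈ {day 3, week 1, week 2}, each indicator's trend relative to
the admission panel is banded:

- TB, Cr (adverse when rising): relative change r > θ → 3; r < −θ → 1;
  |r| ≤ θ → 2;
- PTA (adverse when falling): r < −θ → 3; r > θ → 1; else 2;
- HE stage: aggravated ≥ δ stages → 3; improved ≥ δ → 1; else 2.

Defaults θ = 0.30 and δ = 1; SDTs = sum of the four scores ∈ [4, 12]. The
composite score is a linear predictor with fixed per-unit weights
(0.033 age, 0.326 WGO, −0.672 etiology, 0.082 TB, 0.913 Cr, −0.040 PTA,
0.817 SDTs) and *no* intercept; the logistic constant (−10.441 in the
canonical fit) is carried separately on `DPACLFModel.intercept` because
the grade cuts (8, 12) and reported cutoffs live on the intercept-free
scale. Grade II is closed on both ends: scores of exactly 8 or 12 are
grade II.

Design choices where the procedure was genuinely open:

- **Trend reference.** Trends are computed against admission by default;
  a previous-timepoint reference is available in `TrendConfig` since some
  clinical workflows track interval change instead.
- **PTA banding.** PTA's 30% band is *relative* change (fraction of the
  reference value), parallel to TB and Cr, not absolute
  percentage-points — PTA is itself a percentage, so the two readings
  differ; relative is the default and only implemented variant.
- **Boundary convention.** A change of exactly the threshold scores 2
  (the "within band" reading of ≤).
- **HE stage 0 → 0** counts as "unchanged" (score 2); patients who are
  never encephalopathic are not special-cased.

## Model building

**Threshold scan.** For each candidate band (labs: {0.10…0.50}; HE:
{1,2,3}) the indicator's 1/2/3 trend score is computed for every patient
alive at the landmark, survival is regressed on it by univariate Cox
(lifelines, Efron ties), and Harrell's C of the fitted predictor is
recorded; the chosen band maximizes C, with exact ties broken toward 0.30
(HE: one stage) and then toward the smaller candidate. A constant
indicator yields C = 0.5 without a fit.

**Forward-LR logistic selection.** Candidates enter by the smallest
likelihood-ratio p-value while p < 0.05 and any included variable with
LR p > 0.10 is removed (the variable entered in the current step is
exempt from that step's removal pass, which prevents cycling). Entry and
removal thresholds follow the common stepwise convention since the
procedure's description leaves them open. Separation is detected by
non-finite standard errors or runaway coefficients and raised as a typed
error. The landmark filter keeps patients whose survival strictly exceeds
the landmark offset or who were censored alive at/after it; because that
selection depends on the outcome only, it shifts the logistic intercept
but leaves slopes consistent — parameter-recovery tests fit on the full
simulated cohort where the generating model holds exactly.

**Cox machinery.** Multivariable proportional-hazards fits use lifelines
with Efron tie handling (day-resolution times are heavily tied);
covariates without variation are excluded with a note rather than
failing the batch.

## Evaluation statistics

AUC is the tie-corrected Mann–Whitney estimator; its SE and the paired
z-test for two scores on the same patients use the DeLong
structural-components (midrank) formulation with a two-sided normal p.
Cutoffs maximize Youden's J over observed score values, reporting the
midpoint below the winning threshold so separated classes get the gap
midpoint; positive likelihood ratio is sens/(1−spec), negative
(1−sens)/spec. Harrell's C counts pairs where the strictly-shorter
follow-up ended in death (equal times: usable only when exactly one is a
death, which counts as shorter); predictor ties contribute ½; Somers'
D = 2C − 1 by construction. Kaplan–Meier and the log-rank test come from
lifelines; Pearson's chi-square (no continuity correction) from scipy.
The implementation-independent checks in the test suite enumerate all
pairs/thresholds by brute force and, for DeLong, use a 20,000-replicate
paired swap test.

## The synthetic cohort generator

The generator emulates the *structure* of a hospital ACLF cohort, not any
particular dataset's summary table. Defaults (units in field names):

- covariates: age ~ N(48, 12²) clipped to [18, 90]; WGO type ~ (0.16,
  0.35, 0.49); alcohol-only etiology 19%; HBV the dominant remainder —
  proportions typical of East-Asian ACLF series;
- admission labs: TB log-normal (median 15 mg/dL, log-sd 0.35, floored at
  the 5 mg/dL jaundice inclusion level); Cr log-normal (median 0.9,
  log-sd 0.35); PTA ~ N(32, 7²)% truncated below 40% (the coagulopathy
  inclusion criterion); INR derived from PTA by the monotone map
  0.5 + 40/PTA; HE start distribution (0.62, 0.16, 0.11, 0.07, 0.04);
- trajectories: one latent severity walk per patient, Normal(0, 0.25)
  increment per interval; TB, Cr move as exp(+loading·severity), PTA as
  exp(−loading·severity) (loadings 0.55/0.35/0.30) plus idiosyncratic
  log-noise (sd 0.10); HE evolves by a mostly-stay transition matrix with
  a ±1-stage nudge when the walk moves sharply. The shared walk makes
  adverse trends positively correlated without collinearity;
- outcome: η = published coefficients applied to week-2 features
  (including the true SDTs); death ~ Bernoulli(expit(b + η)) with death
  day uniform on (0, 90] and survivors censored at 90. The default
  constant b = −10.8835 was set once by bisection
  (`calibrate_intercept`) so marginal mortality is ≈ 33.8%, the rate
  typical of such training cohorts; the dispersion defaults above were
  likewise fixed once so the true predictor's week-2 AUC lands near
  0.82–0.83, the discrimination the score family exhibits on real
  cohorts. A `cox` outcome mode (exponential survival, log-hazard = 1.0
  per SD of η, baseline 0.004/day) supports concordance and Cox tests,
  and `planted_threshold_cohort` builds cohorts whose hazard depends only
  on one indicator crossing a known band (hazard ratio 3), for scan
  recovery tests.

What the generator does **not** emulate: competing risk of
transplantation, treatment effects (e.g. artificial liver support),
loss to follow-up before day 90, within-day lab variability, or any
correlation between the comparator-score inputs (WBC, MAP, PaO₂:FiO₂,
ascites) and the severity walk — those fields are drawn independently and
only exercise the comparator calculators' plumbing. Passing tests
therefore demonstrate the machinery's correctness and the procedures'
statistical behaviour under a faithful generating model, not clinical
performance on real patients.

## Problem sizes and numerics

Parameter-recovery checks use one cohort of n = 5,000 (all seven
candidates selected; coefficients within 15% relative error at the fixed
test seed) and 20 replicate cohorts of n = 1,000 for the planted-band
scan. Oracle-equivalence suites run ≥ 100 random instances of size ≤ 15,
where exhaustive enumeration is exact. Logistic fits cap Newton
iterations at 200; Cox fits use lifelines defaults; bisection for the
intercept runs to 10⁻⁴. Degenerate inputs (single-class outcomes,
constant predictors, zero contingency margins, no usable survival pairs)
raise typed errors rather than returning silent NaNs.

## Known limitations

- The forward-LR null behaviour is the procedure's own: with seven
  candidates screened at p < 0.05, about 30% of pure-noise datasets admit
  at least one variable; the suite tests model *size* under the null, not
  emptiness.
- Comparator circulatory sub-scores collapse vasopressor dose tiers to a
  single flag because the data model carries no dose information.
- CTP uses INR bands (the data model has no prothrombin-seconds field);
  the COSSH organ grid reuses the six-organ 0–4 bands.
- Printed likelihood-ratio columns in some published comparator tables
  cannot be reconciled with standard definitions; this package reports
  the standard ones.
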