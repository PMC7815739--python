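# dpaclf

Dynamic prognostic scoring for **acute-on-chronic liver failure (ACLF)** —
a Python library for building and evaluating 90-day mortality models that
combine baseline covariates with the *trends* of clinical indicators over
the first two weeks of admission.

ACLF is an unstable syndrome: patients with similar admission labs can
recover completely or die within weeks, so scores computed from a single
timepoint (CTP, MELD, CLIF-SOFA, …) miss much of the signal. This package
implements a landmark-style dynamic approach for hepatologists and
biostatisticians: each of four indicators — total bilirubin (TB),
creatinine (Cr), prothrombin activity (PTA), and hepatic-encephalopathy
(HE) stage — is scored 1/2/3 by whether it improved beyond, stayed within,
or deteriorated beyond a relative-change band (default 30%, one HE stage)
between admission and a landmark (day 3, week 1, week 2). Their sum, the
**SDTs** (sum of dynamic trend scores, range 4–12), enters a composite
linear score:

```
DP-ACLF = 0.033·age + 0.326·WGO_type + 0.082·TB + 0.913·Cr
          + 0.817·SDTs − 0.040·PTA − 0.672·Etiology
```

with age in years, WGO type 1/2/3 (no cirrhosis / compensated /
decompensated), TB and Cr in mg/dL, PTA in %, and Etiology = 1 for
alcoholic liver disease alone. Patients are graded I (score < 8),
II (8–12), III (> 12).

The package provides, as importable modules with a thin `dpaclf` CLI over
them:

- `dpaclf.cohort` — domain types, long-format CSV I/O, study-flow and
  landmark filtering;
- `dpaclf.trend` — the trend-score bands and SDTs;
- `dpaclf.scores` — the six comparator scores (CTP, MELD, MELD-Na,
  CLIF-SOFA, CLIF-C ACLF, COSSH-ACLF) with auditable band tables;
- `dpaclf.model` — the DP-ACLF formula and grading, Harrell's-C threshold
  scanning, forward likelihood-ratio logistic selection, multivariable Cox;
- `dpaclf.evaluate` — DeLong ROC/AUC machinery, Youden cutoffs,
  Harrell's C / Somers' D, Kaplan–Meier + log-rank, Pearson chi-square;
- `dpaclf.simulate` — a longitudinal synthetic-cohort generator whose
  outcome is driven by a known linear predictor, so every stage is
  testable without patient data;
- `dpaclf.pipeline` — one-call reproducible runs with manifests.

## Worked example

Rebuild the model on a simulated cohort and benchmark it against MELD
(`examples/04_fit_and_evaluate.py`):

```text
variable              generating   refitted
age                       +0.033     +0.034
wgo_type                  +0.326     +0.250
etiology_alcohol_only     -0.672     -0.663
tb                        +0.082     +0.079
cr                        +0.913     +0.910
pta                       -0.040     -0.042
sdts                      +0.817     +0.969

week-2 AUC: DP-ACLF 0.839 (SE 0.010)  MELD 0.753
DeLong z = 8.95, p = 3.43e-19
```

Forward-LR selection rediscovers all seven generating coefficients from
2,000 simulated patients (refitted values wobble within sampling error),
and the dynamic score's week-2 ROC area beats MELD's on the same patients
— as it must, since the simulated outcome depends on the lab *trends* that
a single-timepoint score cannot see. Grade-stratified survival
(`examples/05_grades_and_survival.py`) separates sharply:

```text
grade   n    events   S(28d)   S(90d)
  I     148       2   0.993    0.986
  II   1135     292   0.957    0.743
  III   127     109   0.827    0.142
log-rank chi2 = 370.7 (df 2), p = 3.22e-81
```

Each script in `examples/` is a short, self-contained narrative of one
capability. The same stages are available from the shell:

```sh
dpaclf simulate --n 500 --seed 1 --out-prefix cohort
dpaclf trend cohort_labs.csv cohort_patients.csv --timepoint week1
dpaclf run --n 500 --seed 1 --out-dir my_run
```

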