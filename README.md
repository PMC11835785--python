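# afrelapse

Discrete Bayesian networks for predicting atrial fibrillation (AF)
relapse after percutaneous pulmonary vein isolation (PVI).

Catheter ablation eliminates AF in many patients, but a substantial
fraction relapse after the post-procedural blanking period, and clinical
scores such as ATLAS use a fixed predictor set that is often incomplete at
the point of care (left-atrial volume and epicardial fat require imaging).
`afrelapse` implements an explainable alternative for clinicians and
biostatisticians: a discrete Bayesian network over 12 discretized clinical
variables whose joint distribution factorizes along a clinically
constrained DAG,

    P(x_1, ..., x_12) = prod_i P(x_i | pa(x_i)),

with the outcome node `relapse` fed by seven parents — age, sex, smoking,
preablation AF type, left-atrial volume, epicardial fat, and obstructive
sleep apnea (OSA).  Because prediction is an exact conditional-probability
query, any subset of predictors may be supplied as evidence; missing ones
are simply marginalized, so the same fitted model serves the full
7-predictor setting and the cheaper 5- and 6-predictor bedside settings.

The package provides:

* **Structure learning** — BIC-scored hill climbing over single-arc moves
  under whitelist/blacklist constraints (forced clinical arcs, outcome as
  a sink); deterministic without a seed.
* **Parameter fitting** — Dirichlet posterior means under a uniform
  (BDeu-style) prior with configurable equivalent sample size (default 1).
* **Exact inference** — full-joint enumeration over the 20,736-cell state
  space, with an independent variable-elimination engine as a second
  route.
* **Validation** — the repeated-resampling protocol (bootstrap with
  out-of-bag testing, hold-out 80:20 / 90:10 / 95:5), every patient tested
  ≥ 30 times, per-patient averaged probabilities, ROC-AUC with DeLong 95%
  CI, Youden-J cutoffs.
* **A calibrated synthetic cohort generator** — the original 480-patient
  registry is private, so the package ships its published stratified
  counts and builds a generating network that reproduces every printed
  marginal and outcome-stratified frequency (see `docs/methods.md`).

## Worked example

```python
import afrelapse as ar

# a 480-patient synthetic cohort from the calibrated generator
gt = ar.default_ground_truth()
cohort = ar.sample_cohort(gt, 480, seed=1)

# fit CPTs on the fixed clinical structure and query one patient profile
net = ar.fit_cpts(gt.structure, cohort, equivalent_sample_size=1.0)
res = ar.query(net, "relapse", {"sex": "female", "age": "over65", "smoking": "false"})
print(f"P(relapse | female, +65, non-smoking) = {res['true']:.3f}")

# the four-scheme validation protocol with the 7-predictor set
out = ar.run_all_schemes(cohort, gt.structure, ar.PREDICTOR_SETS["full7"], seed=11)
for label, r in out["per_scheme"].items():
    print(f"{label:12s} AUC {r.auc:.3f} (95% CI {r.auc_ci_low:.3f}-{r.auc_ci_high:.3f})")
print(f"mean AUC {out['mean_auc']:.3f}")
```

Output:

```
P(relapse | female, +65, non-smoking) = 0.288
bootstrap    AUC 0.823 (95% CI 0.785-0.861)
split_80_20  AUC 0.821 (95% CI 0.782-0.859)
split_90_10  AUC 0.822 (95% CI 0.784-0.861)
split_95_5   AUC 0.823 (95% CI 0.785-0.861)
mean AUC 0.822
```

The query answers the bedside question "how likely is this patient to
relapse given what we know", here with only three observed variables (the
other predictors are marginalized).  The validation table reports, for
each resampling scheme, how well per-patient averaged probabilities
rank relapsing above non-relapsing patients (AUC 0.5 = chance, 1.0 =
perfect); the schemes agree closely because they differ only in how
training samples are drawn.  Richer evidence helps: averaged over 20
synthetic cohorts, the mean AUC rises from ≈ 0.68 with the 5 easily
available predictors to ≈ 0.73 when BMI is added (a proxy for its child,
epicardial fat) and ≈ 0.80 with the full 7-predictor set.

The same pipeline is scriptable from the shell:

```sh
afrelapse simulate --n 480 --seed 1 --out cohort.csv
afrelapse learn cohort.csv --out structure.json --dot structure.dot
afrelapse predict cohort.csv --evidence '{"osa": "true"}' --cycles 50
afrelapse validate cohort.csv --predictor-set full7 --scheme all --seed 11 --out metrics.json
```

## Layout

```
src/afrelapse/
  schema.py              12-variable clinical schema, discretization bands
  cohort.py              categorical cohort container, CSV round-trip
  network.py             DAG + CPTs, Bayesian fitting, log-likelihood
  structure_learning.py  BIC, constrained hill climbing, SHD
  inference.py           exact queries by joint enumeration
  elimination.py         independent variable-elimination route
  validation.py          resampling protocol, AUC/CI/Youden
  synthetic.py           stratified-count fixture + calibrated generator
  cli.py                 simulate | learn | fit | predict | validate
  data/                  constraint, calibration and count files (editable)
```

`docs/methods.md` documents the model, the calibration procedure, the
protocol's numerical choices, and what the synthetic benchmarks do and do
not demonstrate about real registry data.
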