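# Methods

## The model

`afrelapse` implements a discrete Bayesian network for estimating the
probability of atrial fibrillation (AF) relapse after percutaneous
pulmonary vein isolation (PVI).  Twelve discretized clinical variables —
sex, age band, alcoholism, smoking, diabetes, high blood pressure (HBP),
obstructive sleep apnea (OSA), BMI class, preablation AF type,
left-atrial-volume band, epicardial-fat band, and the binary outcome
`relapse` — form the nodes of a directed acyclic graph.  The joint
distribution factorizes as

    P(x_1, ..., x_12) = prod_i P(x_i | parents(x_i)),

and each factor is a conditional probability table (CPT).  The outcome
node has seven parents: the five ATLAS-score predictors (age, sex,
smoking, preablation AF type, left-atrial volume) plus epicardial fat and
OSA.  The full state space has 2^8 * 3^4 = 20,736 cells, small enough that
every inferential quantity in this package is computed exactly.

### Structure: clinical whitelist + BIC hill climbing

The graph is built in two stages.  A *whitelist* forces arcs that encode
established clinical knowledge: the seven predictor→outcome arcs, and
risk-factor arcs into the disease nodes (by default `bmi→{diabetes, hbp,
osa}` and `age→{diabetes, hbp}`).  A *blacklist* forbids all arcs out of
the outcome (relapse is a sink).  The remaining structure is learned by
greedy hill climbing over single-arc moves (add / delete / reverse),
scored by the decomposable BIC

    local_i = max-loglik(x_i | parents_i) - (log n)/2 * (r_i - 1) * q_i,

where r_i is the node's state count and q_i the number of parent
configurations.  Whitelist arcs can never be deleted or reversed,
blacklist arcs never added, and acyclicity is preserved at every step.
Moves are enumerated in lexicographic (operation, parent, child) order and
the first maximal improvement is applied, so learning is deterministic
without a seed.  No random restarts or tabu list are used (plain greedy
ascent); the parent count is unbounded by default but can be capped via
`max_parents` to protect CPT size.  The default *risk-factor* whitelist
arcs (`bmi→osa` etc.) live in an editable JSON file
(`src/afrelapse/data/constraints_default.json`) rather than in code, so a
different clinical prior can be swapped in without touching the library;
all structure-dependent tests read that file.

### Parameters: Dirichlet posterior means (BDeu-style uniform prior)

Given a structure, each CPT cell is estimated as the posterior mean under
a uniform Dirichlet prior spread evenly over the table: with equivalent
sample size (ESS) `s`, child cardinality `r` and `q` parent
configurations, every cell receives pseudo-count `s/(r q)` and

    P(x = k | parents = j) = (N_jk + s/(r q)) / (N_j + s/q).

The default ESS is 1, the common default in discrete Bayesian-network
toolkits; the limit ESS→0+ recovers maximum-likelihood frequencies, and a
very large ESS pulls every table to uniform.  ESS is exposed everywhere
(`fit_cpts`, the CLI, the validation loop) because the appropriate prior
weight is a modelling decision, not a constant.

### Inference: exact, by joint enumeration

Queries `P(target | evidence)` are answered exactly: the joint tensor is
assembled once per fitted network (20,736 float64 cells), evidence axes
are fixed by indexing, remaining non-target axes are summed out, and the
result is normalized.  Variables missing from the evidence are thereby
marginalized — this is precisely how the 5-, 6- and 7-predictor
configurations are realized: the same fitted network is queried with
smaller evidence sets, no refitting involved.  Evidence with probability
exactly zero raises `ImpossibleEvidenceError` instead of returning NaN,
because silent NaNs would corrupt downstream AUC computation.  With at
most 12 factors of magnitude ≥ machine-minimum, float64 products cannot
underflow on this schema, so no log-space accumulation is needed.

A second, independently written exact-inference route — factor-based
variable elimination with a min-degree ordering
(`afrelapse.elimination.query_ve`) — exists both as the scalable path for
larger schemas and as the cross-check oracle: the test suite verifies
agreement with enumeration to 1e-9 on 100 random networks.

### Validation protocol

Out-of-sample performance is estimated by repeated resampling with a
*fixed* structure (only CPTs are refit per cycle — a single published
graph, refit probabilities):

1. draw a training sample — bootstrap (n draws with replacement; expected
   distinct fraction 1 − 1/e ≈ 63.2%) or hold-out at ratios 80:20, 90:10,
   95:5;
2. refit CPTs on the training rows (ESS = 1);
3. score every test patient (out-of-bag rows for bootstrap; the held-out
   rows otherwise) with their exact conditional relapse probability under
   the chosen predictor set;
4. repeat whole-cohort cycles until **every** patient has been tested at
   least 30 times (no per-patient targeting — the simplest reading of the
   stopping rule);
5. average each patient's probabilities arithmetically and compute the
   ROC-AUC of the means against the true outcomes.

The AUC confidence interval uses the DeLong placement-value variance with
a normal quantile, truncated to [0, 1]; the suite cross-checks it against
a 2,000-resample percentile bootstrap.  Classification cutoffs maximize
the Youden J statistic (rule: positive iff score ≥ cutoff; J-ties broken
toward the smallest cutoff).  Per-cycle AUCs are also retained for
transparency.  Randomness follows one master seed with per-cycle child
seeds spawned deterministically (`numpy.random.SeedSequence`), making every
run bit-for-bit reproducible.

A subtlety worth knowing: with an *empty* predictor set, each cycle
predicts the training-sample relapse marginal for every test patient.
Across refits that marginal anti-correlates with test membership
(excluding a relapse-positive patient slightly lowers the training
marginal), so the protocol's AUC for an information-free predictor drifts
*below* 0.5 rather than sitting exactly on it.  Truly constant scores give
exactly 0.5 under the tie convention; the near-constant scores produced by
the protocol cannot do better than chance but can do nominally "worse".
This is a property of all leave-out designs with marginal predictors, not
of this implementation.

## The synthetic cohort generator

The registry the model was developed on (480 PVI patients) is not public.
What is public is the stratified count table: for every variable class,
how many patients in total, with relapse, and AF-free.  The generator
turns those counts into a fully specified network:

* **Structure** — the whitelist plus the six data-driven arcs of the
  reference network (`bmi→epicardial_fat`, `osa→af_type`,
  `af_type→la_volume`, `sex→{smoking, alcoholism, bmi}`).
* **Root nodes** (sex, age) take the printed marginals directly.
* **Binary intermediate nodes** use additive log-odds with fixed
  association strengths from `data/calibration_default.json`; the
  intercept is solved (Brent root-finding) so the implied marginal matches
  the printed one exactly.
* **Three-state intermediate nodes** (BMI, epicardial fat, LA volume) use
  an ordinal association `P(k|j) ∝ m_k exp(γ s_j k)` with base weights
  `m_k` fitted by iterative proportional scaling to the printed marginals.
* **The outcome CPT** (432 parent configurations) is a monotone additive
  log-odds form fitted by cyclic margin matching so that every implied
  per-class relapse rate equals its printed value (e.g. 35/50 = 70% among
  OSA-positive patients, 100/152 = 65.8% in the top epicardial-fat band)
  and the overall rate equals 166/480.  A 432-row table is not
  identifiable from one-way margins; the interaction-free additive form is
  the smallest-complexity surrogate consistent with all of them.

The builder verifies every target on the implied distribution (tolerance
5e-3) and raises listing the unmatched margins rather than silently
shipping a distorted generator.  Association strengths are in one editable
JSON file; they were chosen once to be clinically plausible (men smoke and
drink more; BMI strongly drives epicardial fat and OSA; persistent AF
enlarges the atrium) and strong enough to be detectable at n ≈ 20,000.

What the generator does **not** emulate: follow-up durations or any
time-to-event structure; outcome associations for alcoholism, diabetes and
HBP beyond their margins (they are not parents of the outcome in the
reference graph, so the generator keeps them outcome-independent given the
graph — their real-world stratified rates may reflect indirect paths the
published margins cannot identify); interactions among the outcome's
parents; and any within-patient measurement noise.  Consequently, passing
tests demonstrate that the *pipeline* recovers structures, parameters and
predictor-ordering on data with the published margins and a plausible
dependence pattern — they do not certify performance on the real registry,
whose AUCs (≈ 0.75 / 0.70 / 0.66 for 7/6/5 predictors) depend on joint
structure the margins do not determine.  On the synthetic cohorts the
7 ≥ 6 ≥ 5 predictor ordering reproduces, with somewhat higher absolute
AUCs (≈ 0.80 / 0.73 / 0.68 at n = 480) because the additive generator is
cleaner than clinical reality.

## Numerical and design choices

* Interval convention for discretization (from the printed table's bracket
  notation): first band closed at its lower end, interior upper ends
  closed, top band open — a left-atrial volume of exactly 100 mL/m² falls
  in `[0, 100]`.
* BMI class edges 25 and 30 kg/m² (WHO convention); the source names
  classes but not edges.
* CPT rows must normalize to 1 within 1e-9; dual-route inference must
  agree within 1e-9; both are asserted, not assumed.
* Hill-climbing accepts a move only if it improves BIC by more than 1e-9,
  which also makes score-equivalent reversals (equal BIC) non-moves.
* Problem sizes in the test and acceptance suites — cohorts of 480 for
  protocol runs, 20,000 for structure recovery, 50,000 for parameter
  recovery, 200,000 for generator calibration checks — were chosen as the
  smallest sizes at which each asymptotic claim is comfortably visible.
* Exit codes of the CLI: 0 success, 2 input/schema error, 3 infeasible
  statistic (e.g. single-class AUC).

## Known limitations

* Exact enumeration scales as the product of cardinalities; beyond ~10^7
  cells the variable-elimination route should be preferred.
* The generator's additive outcome surface understates interaction
  effects; recovery benchmarks are correspondingly easier than clinical
  data would be.
* The equivalent sample size of the original model's uniform prior is not
  published; absolute CPT values are therefore not reproducible even given
  the margins, and all comparisons in this package are structural or
  rank-based.
* No handling of missing *training* cells (complete-case training is a
  contract); missingness is supported only at query time, where it is
  principled (marginalization).
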