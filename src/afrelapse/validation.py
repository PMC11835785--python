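"""Out-of-sample validation: resampling schemes, averaged probabilities,
ROC-AUC with DeLong confidence intervals, and the Youden cutoff.

The protocol mirrors repeated out-of-sample testing on a clinical registry:
each cycle draws a training sample (bootstrap, or a fixed-ratio hold-out
split), refits the CPTs of a *fixed* network structure on the training
rows, and scores every test-set patient with the exact conditional
probability of relapse given their predictor states.  Cycles repeat until
every patient has been scored at least ``min_tests`` times (default 30);
each patient's final score is the arithmetic mean of their per-cycle
probabilities, and the AUC is computed on these means against the true
outcomes.

Bootstrap training samples contain on average a fraction 1 - 1/e (63.2%)
of the distinct patients; the out-of-bag remainder forms the test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .cohort import Cohort
from .exceptions import (
    ImpossibleEvidenceError,
    InfeasibleStatisticError,
    InvalidParameterError,
)
from .inference import Evidence, predict_cohort, query
from .network import NetworkStructure, fit_cpts

__all__ = [
    "SamplingScheme",
    "ValidationResult",
    "resample",
    "run_validation",
    "run_all_schemes",
    "roc_auc",
    "roc_points",
    "auc_confidence_interval",
    "youden_cutoff",
    "profile_probability_ci",
    "PREDICTOR_SETS",
]

#: Named predictor sets.  "atlas5" are the five established clinical
#: predictors (age, sex, smoking, preablation AF type, OSA); "easy6" adds
#: BMI, the easily measured parent of epicardial fat; "full7" uses all
#: seven parents of the outcome, including the imaging-derived left-atrial
#: volume and epicardial fat.
PREDICTOR_SETS: dict[str, tuple[str, ...]] = {
    "atlas5": ("age", "sex", "smoking", "af_type", "osa"),
    "easy6": ("age", "sex", "smoking", "af_type", "osa", "bmi"),
    "full7": ("age", "sex", "smoking", "af_type", "osa", "la_volume", "epicardial_fat"),
}


@dataclass(frozen=True)
class SamplingScheme:
    """One of the four training-sample generators.

    ``kind`` is "bootstrap" (n draws with replacement; out-of-bag rows are
    the test set) or "holdout" (uniform partition with
    ``floor(train_fraction * n)`` training rows).  ``train_fraction`` is
    ignored for bootstrap.
    """

    kind: str
    train_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.kind not in ("bootstrap", "holdout"):
            raise InvalidParameterError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "holdout" and not 0.0 < self.train_fraction < 1.0:
            raise InvalidParameterError("holdout train_fraction must be in (0, 1)")

    @property
    def label(self) -> str:
        if self.kind == "bootstrap":
            return "bootstrap"
        pct = round(self.train_fraction * 100)
        return f"split_{pct}_{100 - pct}"


#: The four schemes of the validation protocol.
DEFAULT_SCHEMES: tuple[SamplingScheme, ...] = (
    SamplingScheme("bootstrap"),
    SamplingScheme("holdout", 0.80),
    SamplingScheme("holdout", 0.90),
    SamplingScheme("holdout", 0.95),
)


@dataclass(frozen=True)
class ValidationResult:
    """Averaged per-patient probabilities and the resulting ROC summary."""

    per_patient_mean_probability: np.ndarray
    per_patient_test_count: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    youden_cutoff: float
    youden_sensitivity: float
    youden_specificity: float
    scheme: SamplingScheme
    predictor_set: tuple[str, ...]
    n_cycles: int
    seed: int
    cycle_aucs: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme.label,
            "predictor_set": list(self.predictor_set),
            "n_cycles": self.n_cycles,
            "seed": self.seed,
            "auc": self.auc,
            "ci": [self.auc_ci_low, self.auc_ci_high],
            "youden_cutoff": self.youden_cutoff,
            "sensitivity": self.youden_sensitivity,
            "specificity": self.youden_specificity,
            "min_test_count": int(self.per_patient_test_count.min()),
            "per_patient": [
                {"id": i, "mean_p": float(p), "n_tests": int(c)}
                for i, (p, c) in enumerate(
                    zip(self.per_patient_mean_probability, self.per_patient_test_count)
                )
            ],
        }


def resample(
    n: int, scheme: SamplingScheme, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one (train, test) index pair under a sampling scheme.

    Bootstrap: n draws with replacement form the training multiset; the
    never-drawn (out-of-bag) indices form the test set.  Holdout: a uniform
    random partition.  The rare empty test set (tiny n) is retried.
    """
    if n < 2:
        raise InvalidParameterError("need at least 2 rows to resample")
    for _ in range(1000):
        if scheme.kind == "bootstrap":
            train = rng.integers(0, n, size=n)
            test = np.setdiff1d(np.arange(n), train)
        else:
            perm = rng.permutation(n)
            k = int(np.floor(scheme.train_fraction * n))
            train, test = perm[:k], perm[k:]
        if len(test) > 0 and len(train) > 0:
            return train, np.sort(test)
    raise InvalidParameterError("could not draw a non-empty test set")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InfeasibleStatisticError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """(fpr, tpr, threshold) rows of the empirical ROC curve."""
    fpr, tpr, thr = roc_curve(np.asarray(labels), np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr, thr])


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Point AUC and its DeLong variance.

    Uses the placement-value decomposition: V10[i] is the probability that
    a random negative scores below positive i (ties half), V01[j] likewise
    for negatives; var(AUC) = var(V10)/m + var(V01)/n.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placements via midranks (handles ties exactly)
    v10 = np.empty(m)
    v01 = np.empty(n)
    for i, x in enumerate(pos):
        v10[i] = ((neg < x).sum() + 0.5 * (neg == x).sum()) / n
    for j, y in enumerate(neg):
        v01[j] = ((pos > y).sum() + 0.5 * (pos == y).sum()) / m
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    return auc, float(var)


def auc_confidence_interval(
    scores: Sequence[float], labels: Sequence[int], level: float = 0.95
) -> tuple[float, float]:
    """Normal-quantile DeLong interval for the AUC, truncated to [0, 1].

    Degenerate variance (perfect or constant scores) collapses the interval
    to the point estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InfeasibleStatisticError("AUC CI undefined: only one class present")
    auc, var = _delong_variance(scores, labels)
    if var <= 0:
        return auc, auc
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def youden_cutoff(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float]:
    """Cutoff among observed scores maximizing J = sens + spec - 1.

    Classification rule: positive iff score >= cutoff.  Ties in J are
    broken toward the smallest cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InfeasibleStatisticError("Youden cutoff undefined: one class only")
    pos = labels == 1
    best = (-np.inf, np.inf, 0.0, 0.0)
    for cut in np.unique(scores):
        pred = scores >= cut
        sens = float((pred & pos).sum() / pos.sum())
        spec = float((~pred & ~pos).sum() / (~pos).sum())
        j = sens + spec - 1.0
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and cut < best[1]):
            best = (j, cut, sens, spec)
    return best[1], best[2], best[3]


def run_validation(
    cohort: Cohort,
    structure: NetworkStructure,
    predictor_set: Sequence[str],
    scheme: SamplingScheme,
    min_tests: int = 30,
    ess: float = 1.0,
    seed: int = 0,
    max_cycles: int = 100_000,
) -> ValidationResult:
    """The repeated-resampling protocol for one scheme and predictor set.

    The structure is held fixed; only CPTs are refit each cycle.  Cycles
    run whole-cohort and stop after the first cycle at which every patient
    has been tested at least ``min_tests`` times.  Reproducible bit-for-bit
    given (seed, scheme, predictor_set): per-cycle RNG streams are spawned
    deterministically from the master seed.
    """
    outcome = cohort.schema.outcome_name
    if outcome in predictor_set:
        raise InvalidParameterError("predictor set must not contain the outcome")
    labels = cohort.column(outcome)
    if len(np.unique(labels)) < 2:
        raise InfeasibleStatisticError("cohort has a single outcome class")

    n = cohort.n
    prob_sum = np.zeros(n)
    count = np.zeros(n, dtype=np.int64)
    cycle_aucs: list[float] = []
    ss = np.random.SeedSequence(seed)
    n_cycles = 0
    while count.min() < min_tests:
        if n_cycles >= max_cycles:
            raise InvalidParameterError(
                f"minimum test count not reached within {max_cycles} cycles"
            )
        rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
        train_idx, test_idx = resample(n, scheme, rng)
        net = fit_cpts(structure, cohort.subset(train_idx), ess)
        probs = predict_cohort(net, cohort.subset(test_idx), predictor_set)
        np.add.at(prob_sum, test_idx, probs)
        np.add.at(count, test_idx, 1)
        test_labels = labels[test_idx]
        if len(np.unique(test_labels)) == 2 and len(np.unique(probs)) > 1:
            cycle_aucs.append(float(roc_auc_score(test_labels, probs)))
        n_cycles += 1

    mean_p = prob_sum / count
    auc = roc_auc(mean_p, labels)
    lo, hi = auc_confidence_interval(mean_p, labels)
    cut, sens, spec = youden_cutoff(mean_p, labels)
    return ValidationResult(
        per_patient_mean_probability=mean_p,
        per_patient_test_count=count,
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        youden_cutoff=cut,
        youden_sensitivity=sens,
        youden_specificity=spec,
        scheme=scheme,
        predictor_set=tuple(predictor_set),
        n_cycles=n_cycles,
        seed=seed,
        cycle_aucs=np.asarray(cycle_aucs),
    )


def run_all_schemes(
    cohort: Cohort,
    structure: NetworkStructure,
    predictor_set: Sequence[str],
    min_tests: int = 30,
    ess: float = 1.0,
    seed: int = 0,
) -> dict[str, object]:
    """All four schemes plus the mean of their AUCs (the summary-table layout)."""
    results = {}
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(DEFAULT_SCHEMES))]
    for scheme, child in zip(DEFAULT_SCHEMES, child_seeds):
        results[scheme.label] = run_validation(
            cohort, structure, predictor_set, scheme, min_tests, ess, seed=child
        )
    aucs = [r.auc for r in results.values()]
    return {"per_scheme": results, "mean_auc": float(np.mean(aucs))}


def profile_probability_ci(
    cohort: Cohort,
    structure: NetworkStructure,
    evidence: Evidence | dict,
    scheme: SamplingScheme,
    n_cycles: int = 100,
    ess: float = 1.0,
    seed: int = 0,
) -> tuple[float, float, float, int]:
    """Resampling band for the relapse probability of one clinical profile.

    Refits CPTs on ``n_cycles`` training resamples, queries the fixed
    evidence each time, and returns (mean, 2.5th pct, 97.5th pct,
    n_excluded) over the cycle estimates.  Cycles where the evidence is
    impossible under the refit network are excluded and counted.
    """
    if not isinstance(evidence, Evidence):
        evidence = Evidence(evidence)
    outcome = cohort.schema.outcome_name
    if outcome in evidence.assignments:
        raise InvalidParameterError("evidence must not contain the outcome")
    ss = np.random.SeedSequence(seed)
    estimates = []
    excluded = 0
    for child in ss.spawn(n_cycles):
        rng = np.random.Generator(np.random.PCG64(child))
        train_idx, _ = resample(cohort.n, scheme, rng)
        net = fit_cpts(structure, cohort.subset(train_idx), ess)
        try:
            res = query(net, outcome, evidence)
        except ImpossibleEvidenceError:
            excluded += 1
            continue
        estimates.append(float(res.distribution[-1]))
    if not estimates:
        raise InfeasibleStatisticError("evidence impossible in every cycle")
    arr = np.asarray(estimates)
    return (
        float(arr.mean()),
        float(np.percentile(arr, 2.5)),
        float(np.percentile(arr, 97.5)),
        excluded,
    )
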