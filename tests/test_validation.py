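"""Resampling schemes, ROC-AUC, DeLong CI, Youden cutoff, and the
repeated-testing protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afrelapse import (
    InfeasibleStatisticError,
    InvalidParameterError,
    PREDICTOR_SETS,
    SamplingScheme,
    auc_confidence_interval,
    profile_probability_ci,
    resample,
    roc_auc,
    run_validation,
    sample_cohort,
    youden_cutoff,
)


class TestResample:
    def test_holdout_partition_sizes(self):
        rng = np.random.default_rng(0)
        train, test = resample(480, SamplingScheme("holdout", 0.80), rng)
        assert len(train) == 384 and len(test) == 96

    def test_holdout_is_a_partition(self):
        rng = np.random.default_rng(1)
        train, test = resample(100, SamplingScheme("holdout", 0.9), rng)
        assert sorted(np.concatenate([train, test])) == list(range(100))
        assert not set(train) & set(test)

    def test_bootstrap_oob_disjoint_from_train(self):
        rng = np.random.default_rng(2)
        train, test = resample(200, SamplingScheme("bootstrap"), rng)
        assert len(train) == 200
        assert not set(train) & set(test)

    def test_bootstrap_distinct_fraction_near_one_minus_inv_e(self):
        """Across many bootstrap draws the mean fraction of distinct
        training indices approaches 1 - 1/e = 63.2%."""
        rng = np.random.default_rng(3)
        n = 2000
        fracs = [
            len(np.unique(resample(n, SamplingScheme("bootstrap"), rng)[0])) / n
            for _ in range(200)
        ]
        assert np.mean(fracs) == pytest.approx(1 - 1 / np.e, abs=0.005)

    def test_bad_scheme_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            SamplingScheme("holdout", 1.0)
        with pytest.raises(InvalidParameterError):
            SamplingScheme("jackknife")


class TestRocAuc:
    def test_pair_enumeration_example(self):
        """3 of the 4 positive-negative pairs are correctly ordered."""
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == pytest.approx(0.5)

    def test_complement_under_score_negation(self):
        rng = np.random.default_rng(7)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1  # both classes present
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_one_class_rejected(self):
        with pytest.raises(InfeasibleStatisticError):
            roc_auc([0.1, 0.2], [1, 1])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        scores=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=4, max_size=30,
        ),
        shift=st.floats(min_value=-5, max_value=5, allow_nan=False),
    )
    def test_invariance_under_monotone_transform(self, scores, shift):
        """The AUC depends only on the score ordering: any strictly
        increasing transform leaves it unchanged.  Scores are quantized so
        the affine map cannot merge distinct values in floating point."""
        scores = [round(s, 3) for s in scores]
        labels = [i % 2 for i in range(len(scores))]
        base = roc_auc(scores, labels)
        transformed = [3.0 * s + shift for s in scores]
        assert roc_auc(transformed, labels) == pytest.approx(base, abs=1e-12)


class TestAucConfidenceInterval:
    def test_contains_point_estimate_and_truncates(self):
        rng = np.random.default_rng(11)
        labels = rng.integers(0, 2, 480)
        labels[:2] = [0, 1]
        scores = labels * 0.4 + rng.random(480) * 0.6
        lo, hi = auc_confidence_interval(scores, labels)
        auc = roc_auc(scores, labels)
        assert 0.0 <= lo <= auc <= hi <= 1.0

    def test_perfect_separation_upper_bound_truncated(self):
        labels = np.repeat([0, 1], 50)
        scores = np.concatenate([np.linspace(0, 0.4, 50), np.linspace(0.6, 1, 50)])
        lo, hi = auc_confidence_interval(scores, labels)
        assert hi == 1.0

    def test_degenerate_variance_collapses_to_point(self):
        labels = np.repeat([0, 1], 20)
        lo, hi = auc_confidence_interval(np.full(40, 0.5), labels)
        assert lo == hi == pytest.approx(0.5)

    def test_agreement_with_bootstrap_percentile_ci(self):
        """Two independent CI constructions (DeLong normal-quantile vs
        percentile bootstrap with 2000 resamples) agree closely on a
        simulated 480-row score set."""
        rng = np.random.default_rng(13)
        labels = np.repeat([0, 1], 240)
        scores = np.clip(labels * 0.25 + rng.normal(0.4, 0.2, 480), 0, 1)
        lo, hi = auc_confidence_interval(scores, labels)
        boot = []
        idx_pos, idx_neg = np.where(labels == 1)[0], np.where(labels == 0)[0]
        for _ in range(2000):
            bp = rng.choice(idx_pos, len(idx_pos))
            bn = rng.choice(idx_neg, len(idx_neg))
            sel = np.concatenate([bp, bn])
            boot.append(roc_auc(scores[sel], labels[sel]))
        blo, bhi = np.percentile(boot, [2.5, 97.5])
        assert lo == pytest.approx(blo, abs=0.012)
        assert hi == pytest.approx(bhi, abs=0.012)


class TestYoudenCutoff:
    def test_exhaustive_scan_example(self):
        cut, sens, spec = youden_cutoff([0.2, 0.3, 0.6, 0.9], [0, 0, 1, 1])
        assert cut == pytest.approx(0.6)
        assert sens + spec - 1 == pytest.approx(1.0)

    def test_all_ties_give_zero_j(self):
        cut, sens, spec = youden_cutoff([0.4] * 4, [0, 1, 0, 1])
        assert cut == pytest.approx(0.4)
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_inverted_labels_destroy_discrimination(self):
        cut, sens, spec = youden_cutoff([0.2, 0.3, 0.6, 0.9], [1, 1, 0, 0])
        assert sens + spec - 1 <= 0.0 + 1e-12

    def test_ties_in_j_break_to_smallest_cutoff(self):
        # two cutoffs achieve J = 0.5; the smaller must be returned
        cut, _, _ = youden_cutoff([0.1, 0.5, 0.6, 0.9], [0, 1, 0, 1])
        scores = np.array([0.1, 0.5, 0.6, 0.9])
        labels = np.array([0, 1, 0, 1])
        js = {
            c: ((scores >= c) & (labels == 1)).sum() / 2
            + ((scores < c) & (labels == 0)).sum() / 2
            - 1
            for c in np.unique(scores)
        }
        best_j = max(js.values())
        assert js[cut] == pytest.approx(best_j)
        assert cut == min(c for c, j in js.items() if abs(j - best_j) < 1e-12)


class TestRunValidation:
    @pytest.fixture()
    def cohort(self, ground_truth):
        return sample_cohort(ground_truth, 200, seed=55)

    def test_every_patient_tested_at_least_min(self, ground_truth, cohort):
        res = run_validation(
            cohort, ground_truth.structure, PREDICTOR_SETS["full7"],
            SamplingScheme("bootstrap"), min_tests=5, seed=1,
        )
        assert res.per_patient_test_count.min() >= 5
        assert ((res.per_patient_mean_probability >= 0)
                & (res.per_patient_mean_probability <= 1)).all()

    def test_reproducible_bit_for_bit(self, ground_truth, cohort):
        kw = dict(min_tests=3, seed=42)
        a = run_validation(cohort, ground_truth.structure, PREDICTOR_SETS["atlas5"],
                           SamplingScheme("holdout", 0.8), **kw)
        b = run_validation(cohort, ground_truth.structure, PREDICTOR_SETS["atlas5"],
                           SamplingScheme("holdout", 0.8), **kw)
        assert np.array_equal(a.per_patient_mean_probability, b.per_patient_mean_probability)
        assert a.auc == b.auc and a.n_cycles == b.n_cycles

    def test_empty_predictor_set_carries_no_signal(self, ground_truth, cohort):
        """With no evidence every prediction is the training-set relapse
        marginal, so per-patient means are nearly constant and the model
        shows no positive discrimination.  (Exactly constant scores would
        give AUC 0.5 by the tie convention; across refits the marginal
        varies slightly and anti-correlates with out-of-bag membership,
        which can only push the AUC below one half.)"""
        res = run_validation(
            cohort, ground_truth.structure, [], SamplingScheme("bootstrap"),
            min_tests=2, seed=7,
        )
        spread = np.ptp(res.per_patient_mean_probability)
        assert spread < 0.1
        assert res.auc <= 0.5 + 1e-9

    def test_outcome_in_predictor_set_rejected(self, ground_truth, cohort):
        with pytest.raises(InvalidParameterError):
            run_validation(cohort, ground_truth.structure, ["relapse"],
                           SamplingScheme("bootstrap"), min_tests=1, seed=0)

    def test_single_class_cohort_rejected(self, ground_truth):
        from afrelapse import Cohort

        cohort = sample_cohort(ground_truth, 50, seed=3)
        codes = cohort.codes.copy()
        codes[:, cohort.schema.index("relapse")] = 0
        with pytest.raises(InfeasibleStatisticError):
            run_validation(Cohort(cohort.schema, codes), ground_truth.structure,
                           PREDICTOR_SETS["atlas5"], SamplingScheme("bootstrap"),
                           min_tests=1, seed=0)


class TestProfileProbabilityCI:
    def test_single_cycle_band_degenerates_to_point(self, ground_truth):
        cohort = sample_cohort(ground_truth, 200, seed=60)
        mean, lo, hi, excluded = profile_probability_ci(
            cohort, ground_truth.structure,
            {"sex": "female", "age": "over65", "smoking": "false"},
            SamplingScheme("bootstrap"), n_cycles=1, seed=5,
        )
        assert lo == pytest.approx(mean) and hi == pytest.approx(mean)
        assert excluded == 0

    def test_band_widens_with_smaller_training_fraction(self, ground_truth):
        """Fewer training rows mean higher refit variance: averaged over
        seeds, the 95:5 band is narrower than the 80:20 band."""
        cohort = sample_cohort(ground_truth, 480, seed=61)
        ev = {"sex": "male", "age": "46to65", "osa": "true"}
        widths = {}
        for frac in (0.80, 0.95):
            w = []
            for seed in range(5):
                _, lo, hi, _ = profile_probability_ci(
                    cohort, ground_truth.structure, ev,
                    SamplingScheme("holdout", frac), n_cycles=60, seed=seed,
                )
                w.append(hi - lo)
            widths[frac] = np.mean(w)
        assert widths[0.80] > widths[0.95]
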