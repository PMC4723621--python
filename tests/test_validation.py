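"""Double cross-validation, permutation inference, and rank products."""

import numpy as np
import pytest

from metabofuse.discriminant import classify, dummy_code, pls_fit, pls_predict
from metabofuse.validation import (
    PermutationResult,
    compute_class_stats,
    double_cv,
    inner_loo_select_ncomp,
    permutation_test,
    rank_products,
    summarize_discriminators,
)


def _brute_force_inner_select(X, labels, a_max, class_order):
    """Independent inner-LOO oracle built on the public PLS API only."""
    n = X.shape[0]
    errors = np.zeros(a_max, dtype=int)
    for a in range(1, a_max + 1):
        for j in range(n):
            idx = [i for i in range(n) if i != j]
            coding = dummy_code([labels[i] for i in idx], class_order)
            model = pls_fit(X[idx], coding, a)
            pred = classify(pls_predict(model, X[j]), class_order)
            errors[a - 1] += pred != labels[j]
    best = int(np.argmin(errors))  # argmin takes the first minimum: smallest A
    return best + 1, errors


class TestInnerSelection:
    def test_perfectly_separable_selects_one(self, separable_xy):
        X, labels = separable_xy
        assert inner_loo_select_ncomp(X, labels, 5) == 1

    def test_a_max_one(self, separable_xy):
        X, labels = separable_xy
        assert inner_loo_select_ncomp(X, labels, 1) == 1

    def test_matches_brute_force_oracle(self, rng):
        """Kernel selection equals an exhaustive inner CV over all A."""
        n, p = 14, 10
        X = rng.normal(0, 1, (n, p))
        labels = ["a", "b"] * 7
        # put the class signal in a direction PLS needs >1 component for
        X[:, 0] += rng.normal(0, 3, n)
        X[np.array(labels) == "a", 1] += 1.5
        for a_max in (1, 2, 4):
            expected, _ = _brute_force_inner_select(X, labels, a_max, ["a", "b"])
            assert inner_loo_select_ncomp(X, labels, a_max) == expected

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            inner_loo_select_ncomp(np.ones((2, 3)), ["a", "b"], 1)


class TestDoubleCv:
    def test_one_model_per_sample(self, separable_xy):
        X, labels = separable_xy
        res = double_cv(X, labels, a_max=3)
        assert res.n_samples == len(labels)
        assert len(res.predicted_labels) == len(labels)
        assert res.coefs.shape == (len(labels), X.shape[1], 2)

    def test_separable_data_zero_misclassifications(self, separable_xy):
        X, labels = separable_xy
        res = double_cv(X, labels, a_max=3)
        assert res.n_misclassified == 0

    def test_singleton_class_error_names_fold(self, rng):
        X = rng.normal(0, 1, (5, 3))
        with pytest.raises(ValueError, match="lose class 'b'"):
            double_cv(X, ["a", "a", "a", "a", "b"], a_max=1)

    def test_shuffled_labels_near_chance(self, separable_xy):
        """Random labels on real structure classify at chance level.

        Averaged over shuffles because a single leave-one-out run on
        permuted labels is overdispersed relative to a fair coin (the
        training majority votes against the held-out sample's class).
        """
        X, labels = separable_xy
        rng = np.random.default_rng(99)
        n = len(labels)
        n_shuffles = 15
        total = 0
        for _ in range(n_shuffles):
            shuffled = [labels[i] for i in rng.permutation(n)]
            total += double_cv(X, shuffled, a_max=3).n_misclassified
        rate = total / (n_shuffles * n)
        band = 2.576 * np.sqrt(0.25 / (n_shuffles * n))
        assert abs(rate - 0.5) <= 2 * band  # factor 2 absorbs run-to-run clustering

    def test_left_out_sample_cannot_influence_its_model(self, separable_xy):
        """Leakage guard: corrupting the held-out row leaves its model unchanged."""
        X, labels = separable_xy
        res = double_cv(X, labels, a_max=2)
        X_bad = X.copy()
        X_bad[4] = 1e6
        res_bad = double_cv(X_bad, labels, a_max=2)
        assert np.array_equal(res.coefs[4], res_bad.coefs[4])
        assert res.selected_ncomp[4] == res_bad.selected_ncomp[4]

    def test_misclassification_count_order_invariant(self, rng, separable_xy):
        X, labels = separable_xy
        X = X + rng.normal(0, 3, X.shape)  # make it imperfect
        res1 = double_cv(X, labels, a_max=3)
        perm = rng.permutation(len(labels))
        res2 = double_cv(X[perm], [labels[i] for i in perm], a_max=3)
        assert res1.n_misclassified == res2.n_misclassified


class TestPermutationTest:
    def test_p_value_formula(self):
        res = PermutationResult(
            observed=0,
            null_misclassifications=np.ones(99, dtype=int),
            n_permutations=99,
            seed=0,
        )
        assert res.p_value == pytest.approx(1 / 100)

    def test_worst_case_p_is_one(self):
        res = PermutationResult(
            observed=20,
            null_misclassifications=np.full(19, 5),
            n_permutations=19,
            seed=0,
        )
        assert res.p_value == 1.0

    def test_reproducible_given_seed(self, separable_xy):
        X, labels = separable_xy
        a = permutation_test(X, labels, a_max=2, n_permutations=19, seed=5)
        b = permutation_test(X, labels, a_max=2, n_permutations=19, seed=5)
        assert np.array_equal(a.null_misclassifications, b.null_misclassifications)
        assert a.p_value == b.p_value

    def test_separable_data_significant(self, separable_xy):
        X, labels = separable_xy
        res = permutation_test(X, labels, a_max=2, n_permutations=99, seed=1)
        assert res.p_value <= 0.05

    def test_p_decreases_with_effect_size(self, rng):
        """Stronger class structure never looks less significant."""
        n_per, p = 8, 20
        labels = ["a"] * n_per + ["b"] * n_per
        noise = rng.normal(0, 1, (2 * n_per, p))
        ps = []
        for effect in (0.0, 5.0):
            X = noise.copy()
            X[:n_per, :6] += effect
            ps.append(
                permutation_test(X, labels, a_max=2, n_permutations=99, seed=2).p_value
            )
        assert ps[1] <= ps[0]

    def test_too_few_permutations_rejected(self, separable_xy):
        X, labels = separable_xy
        with pytest.raises(ValueError):
            permutation_test(X, labels, n_permutations=10)


class TestRankProducts:
    def _result_with_coefs(self, coefs, labels=None):
        from metabofuse.validation import DoubleCVResult

        n, p, K = coefs.shape
        return DoubleCVResult(
            sample_ids=[f"S{i}" for i in range(n)],
            class_order=["a", "b"][:K],
            true_labels=(labels or ["a"] * n),
            predicted_labels=(labels or ["a"] * n),
            selected_ncomp=np.ones(n, dtype=int),
            coefs=coefs,
            predictions=np.zeros((n, K)),
            variable_names=[f"v{j}" for j in range(p)],
        )

    def test_consistent_top_variable_has_unit_rank_product(self):
        coefs = np.zeros((3, 4, 1))
        coefs[:, 0, 0] = [5.0, 6.0, 7.0]   # always rank 1
        coefs[:, 1, 0] = [1.0, 2.0, 0.5]
        coefs[:, 2, 0] = [0.2, 0.1, 0.3]
        coefs[:, 3, 0] = [0.1, 0.05, 0.2]
        rp = rank_products(self._result_with_coefs(coefs))
        assert rp.geo_mean_rank[0, 0] == pytest.approx(1.0)
        assert rp.log_rank_sum[0, 0] == pytest.approx(0.0)

    def test_log_sum_equals_integer_product(self):
        """exp(sum log rank) reproduces the exact integer rank product."""
        rng = np.random.default_rng(8)
        coefs = rng.normal(0, 1, (4, 6, 2))
        rp = rank_products(self._result_with_coefs(coefs, labels=["a", "b"] * 2))
        for k in range(2):
            int_product = np.prod(rp.ranks[:, :, k], axis=0)
            assert np.allclose(np.exp(rp.log_rank_sum[:, k]), int_product, rtol=1e-10)

    def test_two_model_example(self):
        # variable with ranks 2 and 3 -> product 6, geometric mean sqrt(6)
        coefs = np.zeros((2, 3, 1))
        coefs[0, :, 0] = [3.0, 2.0, 1.0]  # v1 rank 2
        coefs[1, :, 0] = [3.0, 1.0, 2.0]  # v1 rank 3
        rp = rank_products(self._result_with_coefs(coefs))
        assert np.exp(rp.log_rank_sum[1, 0]) == pytest.approx(6.0)
        assert rp.geo_mean_rank[1, 0] == pytest.approx(np.sqrt(6.0))

    def test_ties_get_average_ranks(self):
        coefs = np.zeros((1, 3, 1))
        coefs[0, :, 0] = [2.0, 2.0, 1.0]
        rp = rank_products(self._result_with_coefs(coefs))
        assert rp.ranks[0, :, 0].tolist() == [1.5, 1.5, 3.0]

    def test_variable_order_invariance(self, rng):
        coefs = rng.normal(0, 1, (5, 8, 1))
        rp1 = rank_products(self._result_with_coefs(coefs))
        perm = rng.permutation(8)
        rp2 = rank_products(self._result_with_coefs(coefs[:, perm, :]))
        assert np.allclose(rp1.log_rank_sum[perm, 0], rp2.log_rank_sum[:, 0])

    def test_no_overflow_at_study_scale(self):
        """Log-sum stays finite for 44 models x 1709 variables of worst rank."""
        log_sum_worst = 44 * np.log(1709.0)
        assert np.isfinite(log_sum_worst)
        assert np.exp(log_sum_worst / 44) == pytest.approx(1709.0)

    def test_recovers_injected_discriminators(self, rng):
        """Variables with true class signal collect the lowest rank products."""
        n_per, p = 10, 40
        labels = ["a"] * n_per + ["b"] * n_per
        X = rng.normal(0, 1, (2 * n_per, p))
        X[:n_per, :4] += 2.5
        res = double_cv(X, labels, a_max=3)
        rp = rank_products(res)
        top6 = set(rp.ordering(0)[:6])
        assert {0, 1, 2, 3} <= top6


class TestSummary:
    def test_report_layout_and_flags(self, separable_xy):
        X, labels = separable_xy
        res = double_cv(X, labels, a_max=2)
        rp = rank_products(res)
        stats = compute_class_stats(X, labels, res.class_order)
        report = summarize_discriminators(rp, stats, top_k=10)
        assert len(report) == 10
        assert {"variable", "geo_mean_rank", "mean_a", "sd_a", "level_a"} <= set(
            report.columns
        )
        # discriminating variables (cols 0..9 shifted +4 in class a) flagged higher in a
        top = report.iloc[0]
        j = int(top["variable"].removeprefix("var"))
        if j < 10:
            assert top["level_a"] == "higher" and top["level_b"] == "lower"

    def test_stable_across_reruns(self, separable_xy):
        X, labels = separable_xy
        r1 = double_cv(X, labels, a_max=2)
        r2 = double_cv(X, labels, a_max=2)
        rp1, rp2 = rank_products(r1), rank_products(r2)
        assert np.array_equal(rp1.log_rank_sum, rp2.log_rank_sum)
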