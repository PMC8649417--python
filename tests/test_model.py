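"""Unit and property tests for the graded response model core."""

import numpy as np
import pytest
from scipy.stats import norm

from grmcompare.model import (
    MISSING,
    GroupStructure,
    ItemParameters,
    LatentGrid,
    category_prob,
    cumulative_prob,
    eap_score,
    eap_scores,
    fit_grm_multigroup,
    likelihood_ratio_test,
    loading_from_discrimination,
    marginal_loglik,
    pattern_loglik,
)
from grmcompare.simulate import draw_true_scores, simulate_responses

from conftest import random_item


def dense_grid_posterior(pattern, items, mean=0.0, sd=1.0, n=2001, span=9.0):
    """Independent dense-grid oracle for marginalisation and EAP."""
    x = np.linspace(-span, span, n)
    w = norm.pdf(x, mean, sd)
    w /= w.sum()
    L = np.array([np.exp(pattern_loglik(pattern, items, xi)) for xi in x])
    return x, L * w


class TestItemParameters:
    def test_validation(self):
        with pytest.raises(ValueError):
            ItemParameters(5, 1.0, [0.0, -1.0, 1.0, 2.0])  # not increasing
        with pytest.raises(ValueError):
            ItemParameters(5, -1.0, [-1, 0, 1, 2])  # negative slope
        with pytest.raises(ValueError):
            ItemParameters(5, 1.0, [0.0, 1.0])  # wrong threshold count

    def test_loading_conversion_endpoints(self):
        # logistic slopes 1.7..3.5 correspond to loadings ~0.71..0.90,
        # and 0.5..1.0 to ~0.28..0.51
        assert loading_from_discrimination(1.7) == pytest.approx(0.71, abs=0.005)
        assert loading_from_discrimination(3.5) == pytest.approx(0.90, abs=0.005)
        assert loading_from_discrimination(0.5) == pytest.approx(0.28, abs=0.005)
        assert loading_from_discrimination(1.0) == pytest.approx(0.51, abs=0.005)


class TestCategoryProbabilities:
    def test_cumulative_at_threshold_is_half(self):
        item = ItemParameters(2, 2.0, [0.5])
        assert cumulative_prob(item, 0.5, 1) == pytest.approx(0.5)
        item5 = ItemParameters(5, 1.0, [-1, 0, 1, 2])
        assert cumulative_prob(item5, 0.0, 2) == pytest.approx(0.5)

    def test_cumulative_logistic_value(self):
        # 1 / (1 + e^-1) at theta = 0, v = 1, a = 1, b_1 = -1
        item = ItemParameters(5, 1.0, [-1, 0, 1, 2])
        assert cumulative_prob(item, 0.0, 1) == pytest.approx(
            1.0 / (1.0 + np.exp(-1.0)), abs=1e-10
        )

    def test_cumulative_invalid_category(self):
        item = ItemParameters(2, 2.0, [0.5])
        with pytest.raises(ValueError):
            cumulative_prob(item, 0.0, 2)
        with pytest.raises(ValueError):
            cumulative_prob(item, 0.0, 0)

    def test_category_prob_dichotomous_midpoint(self):
        item = ItemParameters(2, 2.0, [0.5])
        np.testing.assert_allclose(category_prob(item, 0.5), [0.5, 0.5])

    def test_category_two_mass(self):
        # P(u=2) = 0.5 - 1/(1+e) at theta 0 for thresholds [-1,0,1,2]
        item = ItemParameters(5, 1.0, [-1, 0, 1, 2])
        expected = 0.5 - 1.0 / (1.0 + np.exp(1.0))
        assert category_prob(item, 0.0)[2] == pytest.approx(expected, abs=1e-12)

    def test_probabilities_sum_to_one_randomised(self, rng):
        for _ in range(1000):
            item = random_item(rng)
            theta = rng.uniform(-4, 4)
            p = category_prob(item, theta)
            assert np.all(p >= 0)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_cumulative_monotone_in_v_and_theta(self, rng):
        for _ in range(200):
            item = ItemParameters(5, rng.uniform(0.5, 3), np.sort(rng.normal(0, 1.5, 4)))
            theta = rng.uniform(-3, 3)
            cums = [cumulative_prob(item, theta, v) for v in range(1, 5)]
            assert np.all(np.diff(cums) <= 0)
            t1, t2 = sorted(rng.uniform(-3, 3, 2))
            if t1 < t2:
                assert cumulative_prob(item, t1, 1) < cumulative_prob(item, t2, 1)


class TestPatternLoglik:
    def test_all_missing_is_zero(self, toy_items):
        assert pattern_loglik([MISSING] * 3, toy_items, 0.7) == 0.0

    def test_single_item_half(self):
        item = ItemParameters(2, 2.0, [0.5])
        assert pattern_loglik([1], [item], 0.5) == pytest.approx(np.log(0.5))

    def test_local_independence(self, toy_items, rng):
        theta = 0.3
        pattern = [2, 1, 4]
        total = pattern_loglik(pattern, toy_items, theta)
        parts = sum(
            pattern_loglik([pattern[j]], [toy_items[j]], theta) for j in range(3)
        )
        assert total == pytest.approx(parts, abs=1e-12)

    def test_invalid_response_raises(self, toy_items):
        with pytest.raises(ValueError):
            pattern_loglik([5, 0, 0], toy_items, 0.0)


class TestMarginalLoglik:
    def test_dense_grid_oracle(self, toy_items):
        resp_ref = np.array([[0, 1, 4], [2, 0, 2], [4, 1, 0], [-1, 1, 3], [3, 0, -1]])
        resp_foc = np.array([[1, 1, 1], [4, 0, 4], [0, 0, 0], [-1, -1, -1], [2, 1, 3]])
        gs = GroupStructure(0.4, 1.3)
        oracle = 0.0
        for resp, (m, s) in ((resp_ref, (0, 1)), (resp_foc, (0.4, np.sqrt(1.3)))):
            for row in resp:
                _, post = dense_grid_posterior(row, toy_items, m, s)
                oracle += np.log(post.sum())
        mine = marginal_loglik(resp_ref, resp_foc, toy_items, toy_items, gs)
        assert mine == pytest.approx(oracle, rel=1e-6)

    def test_all_missing_contributes_zero(self, toy_items):
        resp = np.array([[1, 0, 2]])
        base = marginal_loglik(
            resp, resp, toy_items, toy_items, GroupStructure()
        )
        with_empty = marginal_loglik(
            np.vstack([resp, [[-1, -1, -1]]]), resp, toy_items, toy_items,
            GroupStructure(),
        )
        assert with_empty == pytest.approx(base, abs=1e-10)

    def test_duplicating_respondents_doubles(self, toy_items):
        resp = np.array([[1, 0, 2], [4, 1, 0]])
        one = marginal_loglik(resp, resp, toy_items, toy_items, GroupStructure())
        two = marginal_loglik(
            np.vstack([resp, resp]), np.vstack([resp, resp]),
            toy_items, toy_items, GroupStructure(),
        )
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_bad_variance_raises(self, toy_items):
        with pytest.raises(ValueError):
            marginal_loglik(
                np.array([[0, 0, 0]]), np.array([[0, 0, 0]]),
                toy_items, toy_items, GroupStructure(0.0, -1.0),
            )


class TestEAP:
    def test_all_missing_returns_prior(self, toy_items):
        mean, sd = eap_score([MISSING] * 3, toy_items)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(1.0, abs=1e-6)

    def test_empty_item_list_warns(self):
        with pytest.warns(UserWarning):
            mean, sd = eap_score([], [])
        assert (mean, sd) == (0.0, 1.0)

    def test_dichotomous_response_ordering(self):
        item = ItemParameters(2, 1.3, [-0.2])
        m1, _ = eap_score([1], [item])
        m0, _ = eap_score([0], [item])
        assert m1 > m0

    def test_dense_grid_oracle(self, toy_items):
        extra = [
            ItemParameters(5, 1.8, [-0.5, 0.2, 0.9, 1.7]),
            ItemParameters(2, 2.5, [-1.1]),
        ]
        items = toy_items + extra
        pattern = [2, 1, 3, 0, 1]
        x, post = dense_grid_posterior(pattern, items)
        post = post / post.sum()
        om = (post * x).sum()
        osd = np.sqrt((post * x**2).sum() - om**2)
        mean, sd = eap_score(pattern, items)
        assert mean == pytest.approx(om, abs=1e-6)
        assert sd == pytest.approx(osd, abs=1e-6)

    def test_monotone_in_single_upgraded_response(self, toy_items, rng):
        for _ in range(25):
            pattern = np.array(
                [rng.integers(0, it.n_categories) for it in toy_items]
            )
            j = int(rng.integers(len(toy_items)))
            if pattern[j] >= toy_items[j].n_categories - 1:
                continue
            up = pattern.copy()
            up[j] += 1
            m_lo, _ = eap_score(pattern, toy_items)
            m_hi, _ = eap_score(up, toy_items)
            assert m_hi >= m_lo

    def test_vectorised_matches_scalar(self, toy_items, rng):
        resp = np.array([[0, 1, 4], [2, -1, 2], [-1, -1, -1]])
        means, sds = eap_scores(resp, toy_items)
        for i, row in enumerate(resp):
            m, s = eap_score(row, toy_items)
            assert means[i] == pytest.approx(m, abs=1e-12)
            assert sds[i] == pytest.approx(s, abs=1e-12)


def _simulate_two_groups(items, n, focal_mean, rng):
    th_r = draw_true_scores(n, 0.0, rng)
    th_f = draw_true_scores(n, focal_mean, rng)
    return (
        simulate_responses(th_r, items, rng),
        simulate_responses(th_f, items, rng),
    )


class TestFit:
    def test_nesting_mean_constraint(self, small_banks, rng):
        bank = small_banks[("polytomous", "high")]
        items = [bank.item(i) for i in rng.choice(bank.size, 5, replace=False)]
        rr, rf = _simulate_two_groups(items, 150, 0.0, rng)
        constrained = fit_grm_multigroup(rr, rf, mean_constraint=True)
        free = fit_grm_multigroup(rr, rf, mean_constraint=False, start=constrained)
        assert free.n_free_parameters == constrained.n_free_parameters + 1
        diff = free.log_likelihood - constrained.log_likelihood
        assert diff >= -1e-4
        assert diff < 3.0  # true focal mean is zero: improvement is small

    def test_nesting_free_items(self, small_banks, rng):
        bank = small_banks[("dichotomous", "high")]
        items = [bank.item(i) for i in rng.choice(bank.size, 5, replace=False)]
        rr, rf = _simulate_two_groups(items, 150, 0.0, rng)
        inv = fit_grm_multigroup(rr, rf)
        plan = np.zeros(5, dtype=bool)
        plan[0] = True  # one anchor keeps the free model identified
        freer = fit_grm_multigroup(rr, rf, invariant=plan, start=inv)
        assert freer.log_likelihood >= inv.log_likelihood - 1e-4
        assert freer.n_free_parameters > inv.n_free_parameters

    def test_reported_loglik_matches_marginal(self, small_banks, rng):
        bank = small_banks[("polytomous", "low")]
        items = [bank.item(i) for i in rng.choice(bank.size, 4, replace=False)]
        rr, rf = _simulate_two_groups(items, 120, 0.5, rng)
        fit = fit_grm_multigroup(rr, rf)
        recomputed = marginal_loglik(
            rr, rf,
            fit.item_estimates["reference"],
            fit.item_estimates["focal"],
            fit.group_estimates,
        )
        assert recomputed == pytest.approx(fit.log_likelihood, abs=1e-6)

    def test_empty_category_collapsed(self, rng):
        # item 0 has an unobserved middle category: the fit collapses it
        # (relabelling 0,1,3,4 -> 0,1,2,3) and still runs
        rr = np.array([[0, 1], [1, 0], [3, 1], [4, 0], [1, 1], [3, 0]] * 5)
        rf = np.array([[0, 0], [4, 1], [3, 1], [1, 0], [4, 1], [0, 0]] * 5)
        fit = fit_grm_multigroup(rr, rf)
        assert fit.diagnostics["merged_items"] == [0]
        assert fit.item_estimates["reference"][0].n_categories == 4
        np.testing.assert_array_equal(fit.category_maps[0], [0, 1, 3, 4])

    def test_mean_constraint_pins_mean(self, small_banks, rng):
        bank = small_banks[("dichotomous", "high")]
        items = [bank.item(i) for i in rng.choice(bank.size, 5, replace=False)]
        rr, rf = _simulate_two_groups(items, 100, 0.5, rng)
        fit = fit_grm_multigroup(rr, rf, mean_constraint=True)
        assert fit.group_estimates.focal_mean == 0.0


class TestLRT:
    def _dummy(self, ll, k):
        return type(
            "F", (), {"log_likelihood": ll, "n_free_parameters": k}
        )()

    def test_equal_likelihoods(self):
        stat, df, p = likelihood_ratio_test(self._dummy(-500.0, 5), self._dummy(-500.0, 4))
        assert stat == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_arithmetic(self):
        stat, df, p = likelihood_ratio_test(
            self._dummy(-1000.0, 6), self._dummy(-1002.0, 5)
        )
        assert stat == pytest.approx(4.0)
        assert df == 1

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(self._dummy(-1.0, 4), self._dummy(-1.0, 4))

    def test_small_negative_clipped(self):
        stat, _, p = likelihood_ratio_test(
            self._dummy(-1000.00001, 5), self._dummy(-1000.0, 4)
        )
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_large_negative_warns(self):
        with pytest.warns(UserWarning):
            stat, _, _ = likelihood_ratio_test(
                self._dummy(-1001.0, 5), self._dummy(-1000.0, 4)
            )
        assert stat == 0.0


class TestLatentGrid:
    def test_default_grid_moments(self, grid):
        assert grid.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (grid.weights @ grid.nodes) == pytest.approx(0.0, abs=1e-12)
        assert (grid.weights @ grid.nodes**2) == pytest.approx(1.0, abs=1e-6)

    def test_shifted_weights(self, grid):
        lw = grid.log_weights(0.5, 1.2)
        w = np.exp(lw)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w @ grid.nodes) == pytest.approx(0.5, abs=1e-4)

    def test_invalid_sd(self, grid):
        with pytest.raises(ValueError):
            grid.log_weights(0.0, 0.0)
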