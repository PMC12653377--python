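"""EM estimation, MAP classification, fit indices, and reliability."""

import numpy as np
import pytest

from cdpath.estimation import (
    MixedCDMFit,
    classification_reliability,
    classify,
    cronbach_alpha,
    em_fit,
    fit_indices,
)
from cdpath.models import ItemParameterSet, item_class_probs, profile_space
from cdpath.qmatrix import QMatrix, ResponseMatrix
from cdpath.simulate import dina_recovery_scenario, simulate_cohort

from conftest import make_responses


def _manual_fit(items, pi, n_obs=10):
    K = max(a for it in items for a in it.required_attributes) + 1
    return MixedCDMFit(
        items=tuple(items),
        class_probs=np.asarray(pi, dtype=float),
        loglik=0.0,
        n_params=sum(it.n_free_params for it in items) + len(pi) - 1,
        n_obs=n_obs,
        n_attributes=K,
        trace=np.zeros(1),
        converged=True,
        n_iter=1,
    )


class TestEMFit:
    def test_dina_parameter_recovery_single_seed(self):
        sc = dina_recovery_scenario(n=2000, seed=11)
        profiles, data = simulate_cohort(sc)
        fit = em_fit(data, sc.q, "DINA", seed=11)
        true_g = np.array([it.params[0] for it in sc.items])
        true_s = np.array([it.params[1] for it in sc.items])
        est_g = np.array([it.params[0] for it in fit.items])
        est_s = np.array([it.params[1] for it in fit.items])
        assert np.mean(np.abs(est_g - true_g)) < 0.02
        assert np.mean(np.abs(est_s - true_s)) < 0.02
        assert np.max(np.abs(np.concatenate([est_g - true_g, est_s - true_s]))) < 0.07
        # class proportions: compare to generating independent-half structure
        true_pi = np.full(2**5, 1 / 32)
        assert np.max(np.abs(fit.class_probs - true_pi)) < 0.03

    def test_single_item_matches_grid_search_mixture(self):
        # one item, one attribute: the saturated fit is a 2-class Bernoulli
        # mixture; its maximized loglik must match a brute-force grid search
        rng = np.random.default_rng(5)
        x = (rng.random(400) < 0.62).astype(np.int8)
        q = QMatrix(np.array([[1]]), ("Item1",), ("A1",))
        data = ResponseMatrix(x.reshape(-1, 1))
        fit = em_fit(data, q, "GDINA", seed=0, max_iter=3000, tol=1e-8)
        n1 = int(x.sum())
        n0 = x.size - n1
        grid = np.linspace(0.001, 0.999, 500)
        best = -np.inf
        for p0 in grid[::10]:
            for p1 in grid[::10]:
                for w in grid[::25]:
                    m = w * p1 + (1 - w) * p0
                    ll = n1 * np.log(m) + n0 * np.log(1 - m)
                    best = max(best, ll)
        assert fit.loglik >= best - 1e-6
        # and never above the analytic maximum at m = mean(x)
        m = n1 / x.size
        assert fit.loglik <= n1 * np.log(m) + n0 * np.log(1 - m) + 1e-6

    def test_trace_nondecreasing(self, q2, rng):
        data = ResponseMatrix(rng.integers(0, 2, size=(60, 3)))
        for fam in ("GDINA", "DINA", "LLM", "RRUM", "ACDM"):
            fit = em_fit(data, q2, fam, seed=3, max_iter=200)
            assert np.all(np.diff(fit.trace) > -1e-8), fam

    def test_final_loglik_matches_brute_force_mixture(self, q2, dina_items_q2, rng):
        profiles = profile_space(2)[rng.integers(0, 4, 50)]
        data = make_responses(rng, profiles, dina_items_q2)
        fit = em_fit(data, q2, "DINA", seed=1)
        P = fit.item_probs()  # J x C
        like = np.ones((50, 4))
        for c in range(4):
            for j in range(3):
                pj = np.clip(P[j, c], 1e-10, 1 - 1e-10)
                like[:, c] *= np.where(data.entries[:, j] == 1, pj, 1 - pj)
        brute = np.log(like @ fit.class_probs).sum()
        assert fit.loglik == pytest.approx(brute, abs=1e-6)

    def test_n_params_accounting(self, q2, rng):
        data = ResponseMatrix(rng.integers(0, 2, size=(40, 3)))
        fit = em_fit(data, q2, ["DINA", "LLM", "GDINA"], seed=0, max_iter=50)
        # 2 (DINA) + 2 (LLM, K*=1) + 4 (GDINA, K*=2) + 3 (pi)
        assert fit.n_params == 2 + 2 + 4 + 3

    def test_mismatched_items_rejected(self, q2, rng):
        data = ResponseMatrix(rng.integers(0, 2, size=(10, 5)))
        with pytest.raises(ValueError):
            em_fit(data, q2)


class TestClassify:
    def test_uninformative_item_gives_uniform_posterior(self):
        item = ItemParameterSet("GDINA", (0,), np.array([0.5, 0.0]))
        fit = _manual_fit([item], [0.25, 0.25, 0.25, 0.25])
        # force K=2 manually: one item requiring A1 in a 2-attribute space
        fit = MixedCDMFit(
            items=(item,), class_probs=np.full(4, 0.25), loglik=0.0,
            n_params=5, n_obs=1, n_attributes=2, trace=np.zeros(1),
            converged=True, n_iter=1,
        )
        data = ResponseMatrix(np.array([[1]]))
        cls = classify(fit, data)
        np.testing.assert_allclose(cls.posterior[0], 0.25)
        assert cls.map_index[0] == 0  # tie broken toward lowest index
        assert cls.map_states[0] == "00"

    def test_matches_brute_force_bayes_table(self, q2, dina_items_q2):
        pi = np.array([0.4, 0.1, 0.2, 0.3])
        fit = MixedCDMFit(
            items=dina_items_q2, class_probs=pi, loglik=0.0, n_params=9,
            n_obs=4, n_attributes=2, trace=np.zeros(1), converged=True, n_iter=1,
        )
        X = np.array([[1, 0, 1], [0, 0, 0], [1, 1, 1], [0, 1, 0]])
        data = ResponseMatrix(X)
        cls = classify(fit, data)
        P = item_class_probs(dina_items_q2, 2)  # J x 4
        for i in range(4):
            joint = pi.copy()
            for j in range(3):
                joint *= np.where(X[i, j] == 1, P[j], 1 - P[j])
            np.testing.assert_allclose(
                cls.posterior[i], joint / joint.sum(), atol=1e-12
            )
        np.testing.assert_allclose(cls.posterior.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(
            cls.marginal_mastery, cls.posterior @ profile_space(2), atol=1e-12
        )

    def test_noise_free_items_recover_profile_exactly(self, q2):
        items = tuple(
            ItemParameterSet("DINA", tuple(q2.required_attributes(j)),
                             np.array([0.0, 0.0]))
            for j in range(3)
        )
        fit = MixedCDMFit(
            items=items, class_probs=np.full(4, 0.25), loglik=0.0, n_params=9,
            n_obs=4, n_attributes=2, trace=np.zeros(1), converged=True, n_iter=1,
        )
        space = profile_space(2)
        X = np.stack([
            [int(np.all(space[c][list(items[j].required_attributes)])) for j in range(3)]
            for c in range(4)
        ])
        cls = classify(fit, ResponseMatrix(X))
        assert cls.map_index.tolist() == [0, 1, 2, 3]
        np.testing.assert_allclose(cls.map_prob, 1.0)


class TestFitIndices:
    def test_information_criterion_arithmetic(self, q2):
        items = (
            ItemParameterSet("DINA", (0, 1), np.array([0.2, 0.1])),
            ItemParameterSet("DINA", (0,), np.array([0.2, 0.1])),
        )
        fit = MixedCDMFit(
            items=items, class_probs=np.full(4, 0.25), loglik=-100.0,
            n_params=10, n_obs=100, n_attributes=2, trace=np.zeros(1),
            converged=True, n_iter=1,
        )
        data = ResponseMatrix(np.random.default_rng(0).integers(0, 2, (100, 2)))
        idx = fit_indices(fit, data)
        assert idx.deviance == pytest.approx(200.0)
        assert idx.aic == pytest.approx(220.0)
        assert idx.bic == pytest.approx(200.0 + 10 * np.log(100))

    def test_deterministic_items_give_zero_rmsea(self, q2):
        items = tuple(
            ItemParameterSet("DINA", tuple(q2.required_attributes(j)),
                             np.array([0.0, 0.0]))
            for j in range(3)
        )
        space = profile_space(2)
        profiles = space[np.repeat(np.arange(4), 5)]
        X = np.stack([
            [int(np.all(p[list(items[j].required_attributes)])) for j in range(3)]
            for p in profiles
        ])
        fit = MixedCDMFit(
            items=items, class_probs=np.full(4, 0.25), loglik=0.0, n_params=9,
            n_obs=20, n_attributes=2, trace=np.zeros(1), converged=True, n_iter=1,
        )
        idx = fit_indices(fit, ResponseMatrix(X))
        assert idx.rmsea == pytest.approx(0.0, abs=1e-8)

    def test_cronbach_alpha_spreadsheet_oracle(self):
        X = np.array([
            [1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 0, 0], [1, 1, 1], [0, 1, 0],
        ], dtype=float)
        total = X.sum(axis=1)
        expected = 3 / 2 * (1 - X.var(axis=0, ddof=1).sum() / total.var(ddof=1))
        assert cronbach_alpha(X) == pytest.approx(expected)

    def test_alpha_undefined_for_constant_scores(self):
        with pytest.raises(ValueError, match="alpha"):
            cronbach_alpha(np.array([[1, 0], [0, 1], [1, 0], [0, 1]]))


class TestReliability:
    def test_noise_free_items_perfectly_reliable(self, q2):
        items = tuple(
            ItemParameterSet("DINA", tuple(q2.required_attributes(j)),
                             np.array([0.0, 0.0]))
            for j in range(3)
        )
        fit = MixedCDMFit(
            items=items, class_probs=np.full(4, 0.25), loglik=0.0, n_params=9,
            n_obs=100, n_attributes=2, trace=np.zeros(1), converged=True, n_iter=1,
        )
        per_attr, mean = classification_reliability(fit, 500, 2, seed=0)
        np.testing.assert_allclose(per_attr, 1.0)
        assert mean == pytest.approx(1.0)

    def test_uninformative_items_give_half(self, q2):
        # g = s = 0.5: responses carry no information, the MAP falls back to
        # the (uniform) prior's tie-break, so agreement per attribute is the
        # base rate 0.5
        items = tuple(
            ItemParameterSet("DINA", tuple(q2.required_attributes(j)),
                             np.array([0.5, 0.5]))
            for j in range(3)
        )
        fit = MixedCDMFit(
            items=items, class_probs=np.full(4, 0.25), loglik=0.0, n_params=9,
            n_obs=100, n_attributes=2, trace=np.zeros(1), converged=True, n_iter=1,
        )
        per_attr, mean = classification_reliability(fit, 4000, 3, seed=1)
        np.testing.assert_allclose(per_attr, 0.5, atol=0.03)

    def test_reading_like_fit_reliability_in_unit_interval(self, q2, rng):
        sc = dina_recovery_scenario(n=500, n_items=8, n_attributes=3, seed=2)
        profiles, data = simulate_cohort(sc)
        fit = em_fit(data, sc.q, "DINA", seed=2)
        per_attr, mean = classification_reliability(fit, 500, 2, seed=3)
        assert np.all((per_attr >= 0) & (per_attr <= 1))
        per_attr2, _ = classification_reliability(fit, 500, 2, seed=3)
        np.testing.assert_array_equal(per_attr, per_attr2)
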