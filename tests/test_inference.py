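import numpy as np
import pandas as pd
import pytest

from pondstress.glm import FitResult
from pondstress.inference import (
    condition_i,
    interaction_candidates,
    interaction_scan,
    prr_test,
    screen_variables,
    selection_permutation_test,
)
from pondstress.selection import BestSubsetAIC, ModelSpec, SelectionResult
from tests.conftest import random_poisson_instance


def _stub_fit(variables, coefs):
    coefs = np.asarray(coefs, dtype=float)
    return FitResult(intercept=1.0, coef=coefs, sigma=0.0, loglik=-10.0,
                     aic=20.0 + 2 * len(coefs), cov=None,
                     fitted=np.ones(5), residuals=np.zeros(5), mixed=False,
                     converged=True, n_free=len(coefs) + 1,
                     names=list(variables))


def _stub_selection(models):
    """models: list of (variables tuple, coef list)."""
    pairs = [(ModelSpec(v, False), _stub_fit(v, c)) for v, c in models]
    return SelectionResult(best_spec=pairs[0][0], best_fit=pairs[0][1],
                           delta_set=pairs, c_delta=2.0)


class TestConditionI:
    def test_absent_from_one_model_fails(self):
        sel = _stub_selection([(("a", "b"), [-1, -2]), (("b",), [-2])])
        assert not condition_i(sel, "a")

    def test_present_everywhere_consistent_sign_passes(self):
        sel = _stub_selection([(("a", "b"), [-1, 2]), (("a",), [-0.5]),
                               (("a", "c"), [-1.5, 0.3])])
        assert condition_i(sel, "a")

    def test_sign_flip_fails(self):
        sel = _stub_selection([(("a", "b"), [-1, 2]), (("a",), [0.5])])
        assert not condition_i(sel, "a")


class TestPRR:
    def test_resolution_guard(self, rng):
        X, y = random_poisson_instance(rng, n_vars=2)
        with pytest.raises(ValueError):
            prr_test(X, y, ModelSpec(("v0", "v1"), False), "v0", B=10)

    def test_focal_must_be_in_model(self, rng):
        X, y = random_poisson_instance(rng, n_vars=3)
        with pytest.raises(ValueError):
            prr_test(X, y, ModelSpec(("v0",), False), "v2", B=99)

    def test_constant_residual_column_gives_p_one(self, rng):
        X, y = random_poisson_instance(rng, n_vars=2)
        X = X.copy()
        X["v1"] = 0.5 * X["v0"] + 0.1  # exact linear function of v0
        p = prr_test(X, y, ModelSpec(("v0", "v1"), False), "v1", B=49,
                     rng=np.random.default_rng(0))
        assert p == 1.0

    def test_extreme_planted_effect_attains_minimum(self, rng):
        X, y = random_poisson_instance(rng, n_ponds=120, n_vars=2,
                                       betas={"v0": -3.5}, intercept=3.5)
        B = 99
        p = prr_test(X, y, ModelSpec(("v0", "v1"), False), "v0", B=B,
                     rng=np.random.default_rng(1))
        assert p == pytest.approx(1 / (B + 1))

    def test_null_type_i_error_calibrated(self, rng):
        # focal independent of response: rejection rate ~ alpha
        rejections = 0
        n_rep = 200
        for i in range(n_rep):
            X, y = random_poisson_instance(rng, n_ponds=30, n_vars=2,
                                           intercept=2.0)
            p = prr_test(X, y, ModelSpec(("v0", "v1"), False), "v0", B=99,
                         rng=np.random.default_rng(1000 + i))
            rejections += p < 0.05
        # binomial(200, 0.05) two-sided 99% band ~ [0.015, 0.10]
        assert 0.015 <= rejections / n_rep <= 0.10

    def test_deterministic_given_seed(self, rng):
        X, y = random_poisson_instance(rng, n_vars=2, betas={"v0": -1.0})
        spec = ModelSpec(("v0", "v1"), False)
        p1 = prr_test(X, y, spec, "v0", B=49, rng=np.random.default_rng(7))
        p2 = prr_test(X, y, spec, "v0", B=49, rng=np.random.default_rng(7))
        assert p1 == p2


class TestSelectionPermutation:
    def test_p_in_valid_range_and_deterministic(self, rng):
        X, y = random_poisson_instance(rng, n_ponds=21, n_vars=4)
        p1 = selection_permutation_test(X, y, "v0", B=49, seed=3,
                                        include_mixed=False)
        p2 = selection_permutation_test(X, y, "v0", B=49, seed=3,
                                        include_mixed=False)
        assert p1 == p2
        assert 1 / 50 <= p1 <= 1.0

    def test_planted_strong_negative_effect_detected(self, rng):
        X, y = random_poisson_instance(rng, n_ponds=100, n_vars=5,
                                       betas={"v1": -2.0}, intercept=3.0)
        p = selection_permutation_test(X, y, "v1", B=99, seed=5,
                                       include_mixed=False)
        assert p <= 0.05

    def test_mixed_and_fast_paths_agree_without_random_effect(self, rng):
        # on equidispersed data every mixed fit collapses to sigma=0, so the
        # mixed-enabled route must reject/accept like the fixed-only route
        X, y = random_poisson_instance(rng, n_ponds=21, n_vars=3,
                                       betas={"v0": -1.5}, intercept=2.5)
        p_fast = selection_permutation_test(X, y, "v0", B=29, seed=11,
                                            include_mixed=False)
        p_full = selection_permutation_test(X, y, "v0", B=29, seed=11,
                                            include_mixed=True)
        assert abs(p_full - p_fast) <= 5 / 30

    def test_unknown_focal_rejected(self, rng):
        X, y = random_poisson_instance(rng, n_vars=2)
        with pytest.raises(ValueError):
            selection_permutation_test(X, y, "nope", B=29)


class TestScreen:
    def test_noncontributive_gets_no_permutation_pvalue(self, rng):
        X, y = random_poisson_instance(rng, n_ponds=21, n_vars=5)
        sel = BestSubsetAIC(include_mixed=False).fit(X, y)
        rep = screen_variables(X, y, sel.result_, prr_B=49, perm_B=49,
                               seed=0, include_mixed=False)
        for v in rep.verdicts:
            if not v.contributive:
                assert v.perm_p is None
                assert v.significant is False

    def test_contributive_requires_all_three_conditions(self, rng):
        X, y = random_poisson_instance(rng, n_ponds=100, n_vars=5,
                                       betas={"v1": -2.0}, intercept=3.0)
        sel = BestSubsetAIC(include_mixed=False).fit(X, y)
        rep = screen_variables(X, y, sel.result_, X_uncontracted=X,
                               member_map={c: [c] for c in X.columns},
                               prr_B=99, perm_B=99, seed=0,
                               include_mixed=False)
        v1 = next(v for v in rep.verdicts if v.variable == "v1")
        assert v1.cond_i and v1.cond_ii and v1.cond_iii and v1.contributive
        assert v1.significant and v1.perm_p < 0.05
        for v in rep.verdicts:
            assert v.contributive == bool(v.cond_i and v.cond_ii and v.cond_iii)


class TestInteractions:
    def test_candidates_include_rescaled_products(self, rng):
        X, _ = random_poisson_instance(rng, n_vars=3)
        from pondstress.contraction import rescale_unit
        Xi = interaction_candidates(rescale_unit(X), ["v0", "v1", "v2"])
        assert {"v0:v1", "v0:v2", "v1:v2"} <= set(Xi.columns)
        assert np.allclose(Xi.min(), 0) and np.allclose(Xi.max(), 1)

    def test_fewer_than_two_mains_is_noop(self, rng):
        X, y = random_poisson_instance(rng, n_vars=3)
        assert interaction_scan(X, y, ["v0"]) is None

    def test_interaction_only_effect_detected(self, rng):
        from pondstress.contraction import rescale_unit
        M = 100
        X = pd.DataFrame({
            "v0": rng.uniform(0, 1, M),
            "v1": (rng.uniform(0, 1, M) > 0.5).astype(float),
        })
        u = rescale_unit(X)
        prod = u["v0"] * u["v1"]
        y = rng.poisson(np.exp(3.0 - 2.5 * prod))
        rep = interaction_scan(X, y, ["v0", "v1"], include_mixed=False,
                               prr_B=99, perm_B=99, seed=2)
        assert rep is not None
        assert "v0:v1" in rep.selection.best_spec.variables
        v = next(x for x in rep.verdicts if x.variable == "v0:v1")
        assert v.coefficient < 0

    def test_null_interaction_not_reported_as_better(self, rng):
        X, y = random_poisson_instance(rng, n_ponds=100, n_vars=2,
                                       betas={"v0": -1.0, "v1": -1.0},
                                       intercept=3.0)
        mains_best = BestSubsetAIC(include_mixed=False).fit(X, y)
        rep = interaction_scan(X, y, ["v0", "v1"], include_mixed=False,
                               prr_B=29, perm_B=29, seed=4,
                               mains_best_aic=mains_best.best_fit_.aic)
        if rep is not None:  # accepted only when AIC is no higher
            assert rep.selection.best_fit.aic <= mains_best.best_fit_.aic + 1e-9
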