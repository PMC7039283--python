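"""Conditional logit: difference design, likelihood calculus, fitting,
fit indices and coding selection."""

import numpy as np
import pytest

from ohsspref.data import ChoiceDataset
from ohsspref.design import (AttributeSpec, ChoiceSet, DesignPlan, Profile,
                             build_design)
from ohsspref.mnl import (EstimationError, build_difference_matrix,
                          default_coding, fit_indices, fit_mnl, information,
                          negloglik, score, select_coding)
from ohsspref.simulate import (SimulationConfig, overall_reference_beta,
                               simulate_study, single_class_population)
import pandas as pd


def _tiny_plan():
    schema = (AttributeSpec("ohss", (0, 5, 10)),
              AttributeSpec("cost", (0, 1000), continuous_scale=1000.0))
    sets = (
        ChoiceSet("s1", Profile((1, 0)), Profile((2, 0))),   # ohss 5 vs 10
        ChoiceSet("s2", Profile((0, 1)), Profile((0, 0))),   # cost 1000 vs 0
        ChoiceSet("s3", Profile((0, 1)), Profile((0, 1))),   # identical
    )
    pool = tuple(p for cs in sets for p in cs.alternatives)
    return DesignPlan(schema, pool, sets)


def _records_for_choices(plan, choices):
    rows = []
    for rid, per_set in choices.items():
        for cs in plan.choice_sets:
            for alt, prof in (("A", cs.a), ("B", cs.b)):
                row = {"respondent_id": rid, "choice_set_id": cs.id,
                       "alternative": alt,
                       "chosen": 1 if per_set[cs.id] == alt else 0}
                row.update(prof.values(plan.schema))
                rows.append(row)
    resp = pd.DataFrame({"respondent_id": list(choices)})
    return ChoiceDataset(pd.DataFrame(rows), resp)


class TestDifferenceMatrix:
    def test_identical_alternatives_give_zero_row(self):
        plan = _tiny_plan()
        ds = _records_for_choices(
            plan, {"r1": {"s1": "A", "s2": "A", "s3": "B"}})
        X, y, _, labels = build_difference_matrix(ds, plan,
                                                  default_coding(plan.schema))
        assert np.all(X[2] == 0.0)

    def test_attribute_difference_coding(self):
        plan = _tiny_plan()
        ds = _records_for_choices(
            plan, {"r1": {"s1": "A", "s2": "A", "s3": "A"}})
        X, y, _, labels = build_difference_matrix(ds, plan,
                                                  default_coding(plan.schema))
        j = labels.index("ohss")
        assert X[0, j] == pytest.approx(-5.0)  # 5% minus 10%
        assert np.all(np.delete(X[0], j) == 0.0)
        assert y[0] == 1.0
        assert X[1, labels.index("cost")] == pytest.approx(1.0)  # per €1000

    def test_row_count_91_by_14(self, cascade, plan):
        _, analysis, _ = cascade
        X, y, rids, _ = build_difference_matrix(analysis, plan,
                                                default_coding(plan.schema))
        assert X.shape[0] == 91 * 14 == 1274
        assert len(np.unique(rids)) == 91

    def test_unanswered_set_raises(self, cascade, plan):
        dataset, _, _ = cascade  # still contains incomplete respondents
        with pytest.raises(EstimationError, match="exclude"):
            build_difference_matrix(dataset, plan,
                                    default_coding(plan.schema))


class TestLikelihoodCalculus:
    def _instance(self, n=40, p=3, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = (rng.random(n) < 0.5).astype(float)
        beta = rng.normal(scale=0.5, size=p)
        return beta, X, y

    def test_zero_beta_is_n_log_2(self):
        _, X, y = self._instance()
        assert negloglik(np.zeros(3), X, y) == pytest.approx(
            len(y) * np.log(2.0))

    def test_perfect_prediction_loglik_to_zero(self):
        X = np.array([[10.0]])
        y = np.array([1.0])
        assert negloglik(np.array([5.0]), X, y) < 1e-20

    def test_gradient_matches_finite_differences(self):
        beta, X, y = self._instance(seed=3)
        g = score(beta, X, y)
        h = 1e-6
        fd = np.array([
            (negloglik(beta + h * e, X, y) - negloglik(beta - h * e, X, y))
            / (2 * h)
            for e in np.eye(len(beta))
        ])
        assert np.allclose(g, fd, rtol=1e-6, atol=1e-8)

    def test_information_matches_finite_difference_of_score(self):
        beta, X, y = self._instance(seed=4)
        H = information(beta, X, y)
        h = 1e-6
        fd = np.column_stack([
            (score(beta + h * e, X, y) - score(beta - h * e, X, y)) / (2 * h)
            for e in np.eye(len(beta))
        ])
        assert np.allclose(H, fd, rtol=1e-5, atol=1e-7)

    def test_negloglik_equals_probability_product_oracle(self):
        from scipy.special import expit

        beta, X, y = self._instance(n=12, seed=5)
        prob = 1.0
        for xi, yi in zip(X, y):
            p = expit(xi @ beta)
            prob *= p if yi == 1 else (1 - p)
        assert negloglik(beta, X, y) == pytest.approx(-np.log(prob))

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(EstimationError):
            negloglik(np.array([np.inf]), np.ones((2, 1)), np.zeros(2))


class TestFit:
    def test_parameter_recovery_within_3_se(self, recovery_small, plan):
        fit = fit_mnl(recovery_small, plan)
        truth = overall_reference_beta()
        assert fit.converged
        for lab, b, se in zip(fit.labels, fit.beta, fit.se):
            assert abs(b - truth[lab]) < 3 * se

    def test_matches_statsmodels(self, recovery_small, plan):
        sm = pytest.importorskip("statsmodels.api")
        coding = default_coding(plan.schema)
        X, y, _, _ = build_difference_matrix(recovery_small, plan, coding)
        res = sm.Logit(y, X).fit(disp=0)
        fit = fit_mnl(recovery_small, plan, coding)
        assert np.allclose(res.params, fit.beta, atol=1e-6)
        assert np.allclose(res.cov_params(), fit.covariance, atol=1e-8)

    def test_refit_is_bit_identical(self, recovery_small, plan):
        a = fit_mnl(recovery_small, plan)
        b = fit_mnl(recovery_small, plan)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.covariance, b.covariance)

    def test_balanced_choices_give_zero_beta(self):
        plan = _tiny_plan()
        # two respondents answering every set in opposite directions
        ds = _records_for_choices(plan, {
            "r1": {"s1": "A", "s2": "A", "s3": "A"},
            "r2": {"s1": "B", "s2": "B", "s3": "B"},
        })
        fit = fit_mnl(ds, plan)
        assert fit.converged
        assert np.allclose(fit.beta, 0.0, atol=1e-8)

    def test_label_swap_leaves_attribute_betas_unchanged(self, recovery_small,
                                                         plan):
        # swapping the A/B roles of every set negates the difference rows
        # and flips y; the attribute estimates must be unchanged
        from ohsspref.mnl import newton_logit

        coding = default_coding(plan.schema)
        X, y, _, _ = build_difference_matrix(recovery_small, plan, coding)
        beta, _, _ = newton_logit(X, y)
        beta_swapped, _, _ = newton_logit(-X, 1.0 - y)
        assert np.allclose(beta, beta_swapped, atol=1e-6)

    def test_optimum_beats_null(self, recovery_small, plan):
        fit = fit_mnl(recovery_small, plan)
        assert fit.loglik >= fit.null_loglik


class TestFitIndices:
    def test_formulas_against_hand_computation(self, recovery_small, plan):
        fit = fit_mnl(recovery_small, plan)
        idx = fit_indices(fit)
        ll, k, n = fit.loglik, fit.n_params, fit.n_obs
        assert idx["AIC"] == pytest.approx(-2 * ll + 2 * k)
        assert idx["cAIC"] == pytest.approx(-2 * ll + k * (np.log(n) + 1))
        assert idx["pseudo_r2"] == pytest.approx(1 - ll / (-n * np.log(2)))

    def test_pseudo_r2_bounds(self, recovery_small, plan):
        fit = fit_mnl(recovery_small, plan)
        r2 = fit_indices(fit)["pseudo_r2"]
        assert 0.0 < r2 < 1.0


class TestSelectCoding:
    def _simulate(self, beta, seed, n=1200):
        plan = build_design(seed=0)
        config = SimulationConfig(n_invited=n, response_rate=1.0,
                                  incomplete_rate=0.0, careless_rate=0.0,
                                  seed=seed)
        ds, _ = simulate_study(n=n, plan=plan,
                               pop_model=single_class_population(beta),
                               config=config, seed=seed)
        from ohsspref.data import apply_exclusions
        analysis, _ = apply_exclusions(ds, plan)
        return analysis, plan

    def test_linear_effect_selects_continuous(self):
        beta = dict(overall_reference_beta())
        # injections exactly linear: 4 and 20 proportional to count
        beta["injections:4"] = -0.04 * 4
        beta["injections:20"] = -0.04 * 20
        analysis, plan = self._simulate(beta, seed=21)
        sel = select_coding(analysis, plan, "injections")
        assert sel.chosen == "continuous"

    def test_nonlinear_injections_select_categorical(self):
        beta = dict(overall_reference_beta())
        beta["injections:4"] = -0.05   # 0 and 4 nearly equivalent
        beta["injections:20"] = -2.0   # 20 much worse
        analysis, plan = self._simulate(beta, seed=22)
        sel = select_coding(analysis, plan, "injections")
        assert sel.chosen == "categorical"
        assert set(sel.level_coefficients) == {"4", "20"}

    def test_two_level_attribute_continuous_by_convention(self):
        plan = _tiny_plan()
        ds = _records_for_choices(plan, {
            "r1": {"s1": "A", "s2": "A", "s3": "A"},
            "r2": {"s1": "A", "s2": "B", "s3": "B"},
            "r3": {"s1": "B", "s2": "A", "s3": "A"},
        })
        sel = select_coding(ds, plan, "cost")
        assert sel.chosen == "continuous"
        assert sel.aic_continuous == pytest.approx(sel.aic_categorical)
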