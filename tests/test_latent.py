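"""Latent-class EM: likelihood oracle, monotonicity, recovery, selection,
assignment and the membership regression."""

import numpy as np
import pandas as pd
import pytest

from ohsspref.data import apply_exclusions
from ohsspref.design import build_design
from ohsspref.latent import (LatentClassFit, assign_classes, em_fit,
                             information_criteria, lc_loglik,
                             membership_logistic, model_selection)
from ohsspref.mnl import (EstimationError, beta_from_dict, default_coding,
                          fit_mnl)
from ohsspref.simulate import (SimulationConfig, choice_probability,
                               reference_population, simulate_study,
                               single_class_population)


def _mixture_dataset(n, seed, pop=None, plan=None):
    if plan is None:
        plan = build_design(seed=0)
    if pop is None:
        pop = reference_population()
    config = SimulationConfig(n_invited=n, response_rate=1.0,
                              incomplete_rate=0.0, careless_rate=0.0,
                              seed=seed)
    ds, _ = simulate_study(n=n, plan=plan, pop_model=pop, config=config,
                           seed=seed)
    analysis, _ = apply_exclusions(ds, plan)
    return analysis, plan


@pytest.fixture(scope="module")
def small_mixture():
    return _mixture_dataset(400, seed=31)


@pytest.fixture(scope="module")
def small_mixture_fit(small_mixture):
    analysis, plan = small_mixture
    fit = em_fit(analysis, plan, K=2, n_starts=5, seed=0)
    return analysis, plan, fit


class TestMixtureLoglik:
    def test_k1_equals_conditional_logit(self, recovery_small, plan):
        fit = fit_mnl(recovery_small, plan)
        ll = lc_loglik([fit.beta], [1.0], recovery_small, plan)
        assert ll == pytest.approx(fit.loglik, abs=1e-9)

    def test_identical_classes_ignore_shares(self, recovery_small, plan):
        fit = fit_mnl(recovery_small, plan)
        lls = [
            lc_loglik([fit.beta, fit.beta], [s, 1 - s], recovery_small, plan)
            for s in (0.1, 0.5, 0.9)
        ]
        assert np.ptp(lls) < 1e-9

    def test_matches_exhaustive_enumeration_oracle(self, schema):
        # 3 respondents, 2 sets: sum over per-respondent class assignments
        from ohsspref.design import (DesignPlan, enumerate_full_factorial,
                                     pair_profiles)
        ff = enumerate_full_factorial(schema)
        pool = [ff[0], ff[100], ff[300], ff[575]]
        plan = DesignPlan(schema, tuple(pool),
                          tuple(pair_profiles(pool, seed=5)))
        pop = reference_population()
        config = SimulationConfig(n_invited=3, response_rate=1.0,
                                  incomplete_rate=0.0, careless_rate=0.0,
                                  seed=6)
        ds, _ = simulate_study(n=3, plan=plan, pop_model=pop, config=config,
                               seed=6)
        analysis, _ = apply_exclusions(ds, plan)
        coding = default_coding(schema)
        betas = [beta_from_dict(b, schema, coding) for b in pop.class_betas]
        shares = np.asarray(pop.class_shares)

        # independent oracle: per respondent, total over classes of
        # share_k times the product of per-set choice probabilities
        oracle = 0.0
        rec = analysis.records
        for rid, grp in rec.groupby("respondent_id"):
            per_class = []
            for b in pop.class_betas:
                prob = 1.0
                for cs in plan.choice_sets:
                    p_a = choice_probability(cs, b, schema, coding)
                    chose_a = grp.loc[(grp["choice_set_id"] == cs.id)
                                      & (grp["chosen"] == 1),
                                      "alternative"].iloc[0] == "A"
                    prob *= p_a if chose_a else 1.0 - p_a
                per_class.append(prob)
            oracle += np.log(float(shares @ np.array(per_class)))

        ll = lc_loglik(betas, shares, analysis, plan)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_invalid_shares_rejected(self, recovery_small, plan):
        with pytest.raises(EstimationError):
            lc_loglik([np.zeros(6)], [0.7], recovery_small, plan)


class TestEMFit:
    def test_loglik_trace_monotone(self, small_mixture_fit):
        _, _, fit = small_mixture_fit
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-8)

    def test_k1_reproduces_conditional_logit(self, recovery_small, plan):
        em = em_fit(recovery_small, plan, K=1, n_starts=1, seed=0,
                    compute_covariance=False)
        fit = fit_mnl(recovery_small, plan)
        assert np.allclose(em.class_betas[0], fit.beta, atol=1e-6)
        assert em.loglik == pytest.approx(fit.loglik, abs=1e-6)
        assert em.shares[0] == pytest.approx(1.0)

    def test_classes_sorted_by_descending_share(self, small_mixture_fit):
        _, _, fit = small_mixture_fit
        assert np.all(np.diff(fit.shares) <= 0)

    def test_posterior_rows_sum_to_one(self, small_mixture_fit):
        _, _, fit = small_mixture_fit
        assert np.allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-10)
        # shares equal posterior column means at convergence
        assert np.allclose(fit.posteriors.mean(axis=0), fit.shares, atol=5e-3)

    def test_final_loglik_consistent_with_lc_loglik(self, small_mixture_fit):
        analysis, plan, fit = small_mixture_fit
        ll = lc_loglik(list(fit.class_betas), fit.shares, analysis, plan)
        assert ll == pytest.approx(fit.loglik, abs=1e-6)

    def test_deterministic_given_seed(self, small_mixture):
        analysis, plan = small_mixture
        a = em_fit(analysis, plan, K=2, n_starts=3, seed=1,
                   compute_covariance=False)
        b = em_fit(analysis, plan, K=2, n_starts=3, seed=1,
                   compute_covariance=False)
        assert np.array_equal(a.class_betas, b.class_betas)
        assert np.array_equal(a.shares, b.shares)


class TestModelSelection:
    def test_two_class_truth_prefers_k2(self, small_mixture):
        analysis, plan = small_mixture
        fits = {K: em_fit(analysis, plan, K=K, n_starts=4, seed=2,
                          compute_covariance=False)
                for K in (1, 2)}
        sel = model_selection(fits)
        assert sel.chosen_K == 2
        assert set(sel.table.columns) >= {"K", "cAIC", "aBIC"}

    def test_single_class_truth_prefers_k1(self):
        analysis, plan = _mixture_dataset(
            300, seed=33, pop=single_class_population())
        fits = {K: em_fit(analysis, plan, K=K, n_starts=4, seed=3,
                          compute_covariance=False)
                for K in (1, 2)}
        assert model_selection(fits).chosen_K == 1

    def test_index_formulas(self, small_mixture_fit):
        _, _, fit = small_mixture_fit
        idx = information_criteria(fit)
        n, k, ll = fit.n_respondents, fit.n_params, fit.loglik
        assert idx["cAIC"] == pytest.approx(-2 * ll + k * (np.log(n) + 1))
        assert idx["aBIC"] == pytest.approx(-2 * ll + k * np.log((n + 2) / 24))

    def test_tie_breaks_to_smaller_k(self, small_mixture_fit):
        _, _, fit = small_mixture_fit
        twin = LatentClassFit(**{**fit.__dict__})
        sel = model_selection({2: fit, 3: twin})  # identical indices
        assert sel.chosen_K == 2


class TestAssignment:
    def test_argmax_and_tie_break(self, small_mixture_fit):
        _, _, fit = small_mixture_fit
        twin = LatentClassFit(**{**fit.__dict__})
        twin.posteriors = np.array([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]])
        twin.respondent_ids = ["r1", "r2", "r3"]
        assigned = assign_classes(twin)
        assert list(assigned) == [0, 0, 1]

    def test_recovery_accuracy(self, small_mixture_fit):
        analysis, plan, fit = small_mixture_fit
        assigned = assign_classes(fit)
        truth = analysis.respondents.set_index("respondent_id")[
            "class_true"].loc[assigned.index]
        # align labels: generator class order need not match share order
        acc = max((assigned == truth).mean(),
                  (assigned == 1 - truth).mean())
        assert acc >= 0.90


class TestMembershipRegression:
    def _assignments(self, n, seed, effect):
        rng = np.random.default_rng(seed)
        age = rng.integers(21, 40, size=n).astype(float)
        x = (rng.random(n) < 0.4).astype(float)
        eta = -0.5 + effect * x
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        cov = pd.DataFrame({
            "respondent_id": [f"r{i}" for i in range(n)],
            "age": age, "prior_cancellation": x,
        })
        assignments = pd.Series(y, index=cov["respondent_id"], name="class")
        return assignments, cov

    def test_null_covariate_near_zero(self):
        assignments, cov = self._assignments(2000, seed=41, effect=0.0)
        res = membership_logistic(assignments, cov, ["prior_cancellation"])
        row = res.univariate.set_index("variable").loc["prior_cancellation"]
        assert abs(row["coef"]) < 3 * row["se"]

    def test_known_log_odds_recovered(self):
        assignments, cov = self._assignments(3000, seed=42, effect=0.8)
        res = membership_logistic(assignments, cov, ["prior_cancellation"])
        row = res.univariate.set_index("variable").loc["prior_cancellation"]
        assert abs(row["coef"] - 0.8) < 3 * row["se"]

    def test_more_than_two_variables_refused(self):
        assignments, cov = self._assignments(200, seed=43, effect=0.5)
        cov["extra"] = 1.0 * (np.arange(len(cov)) % 2)
        with pytest.raises(EstimationError, match="two variables"):
            membership_logistic(assignments, cov, ["extra"],
                                multivariable=["age", "prior_cancellation",
                                               "extra"])

    def test_screening_rule_blocks_weak_variables(self):
        assignments, cov = self._assignments(2000, seed=44, effect=0.0)
        res = membership_logistic(assignments, cov, ["prior_cancellation"])
        # a-priori variables always eligible
        assert "age" in res.eligible and "prior_cancellation" in res.eligible
        cov["noise"] = np.random.default_rng(45).normal(size=len(cov))
        res2 = membership_logistic(assignments, cov, ["noise"])
        if res2.univariate.set_index("variable").loc["noise", "p"] >= 0.15:
            with pytest.raises(EstimationError, match="not eligible"):
                membership_logistic(assignments, cov, ["noise"],
                                    multivariable=["age", "noise"])
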