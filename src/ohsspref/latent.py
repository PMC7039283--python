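"""Latent-class conditional logit via expectation-maximization.

Preference heterogeneity is modelled as a finite mixture: each
respondent belongs to one of K unobserved classes, each with its own
conditional-logit coefficient vector; all of a respondent's answers
share one class, so the mixture log-likelihood is

    l = sum_i log sum_k pi_k prod_t P(choice_it | beta_k).

EM alternates posterior class memberships (E) with share updates and
tau-weighted logit maximum likelihood per class (M); the likelihood is
non-decreasing at every iteration.  Model selection uses consistent AIC
and sample-size-adjusted BIC with the number of respondents (the
independent units of the panel) as n.  After fitting, respondents are
hard-assigned to their highest-posterior class and class membership can
be related to covariates by univariate and small multivariable logistic
regressions.

The sampling covariance reported by :func:`em_fit` is the inverse
observed information of the full mixture log-likelihood in
(class betas, share log-odds), obtained by finite differences of the
analytic mixture score, so the per-class standard errors account for
membership uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .data import ChoiceDataset
from .design import DesignPlan
from .mnl import (CodingScheme, EstimationError, MNLFit,
                  build_difference_matrix, default_coding, information,
                  newton_logit)

__all__ = [
    "LatentClassFit",
    "lc_loglik",
    "em_fit",
    "model_selection",
    "assign_classes",
    "membership_logistic",
    "format_lc_table",
]


def _stack(dataset, plan, coding):
    X, y, rids, labels = build_difference_matrix(dataset, plan, coding)
    uniq, groups = np.unique(rids, return_inverse=True)
    return X, y, groups, list(uniq), labels


def _respondent_class_loglik(X, y, groups, n_resp, class_betas):
    """Matrix L[i, k] = sum_t log P(choice_it | beta_k)."""
    K = len(class_betas)
    L = np.zeros((n_resp, K))
    for k, beta in enumerate(class_betas):
        z = X @ beta
        row_ll = -(np.logaddexp(0.0, z) - y * z)
        L[:, k] = np.bincount(groups, weights=row_ll, minlength=n_resp)
    return L


def lc_loglik(class_betas, shares, dataset: ChoiceDataset, plan: DesignPlan,
              coding: CodingScheme | None = None) -> float:
    """Mixture log-likelihood of a latent-class conditional logit."""
    if coding is None:
        coding = default_coding(plan.schema)
    shares = np.asarray(shares, dtype=float)
    if len(shares) != len(class_betas):
        raise EstimationError("one share per class required")
    if np.any(shares < 0) or abs(shares.sum() - 1.0) > 1e-9:
        raise EstimationError("shares must form a probability vector")
    X, y, groups, uniq, _ = _stack(dataset, plan, coding)
    betas = [np.asarray(b, dtype=float) for b in class_betas]
    L = _respondent_class_loglik(X, y, groups, len(uniq), betas)
    with np.errstate(divide="ignore"):
        return float(logsumexp(L + np.log(shares), axis=1).sum())


@dataclass
class LatentClassFit:
    """A fitted K-class mixture of conditional logits.

    Classes are sorted by descending share, so class 1 is always the
    largest.  ``posteriors`` is the respondent-by-class membership
    matrix tau; ``covariance`` (when computed) is the full-mixture
    observed-information covariance over (betas, share log-odds) and
    ``class_covariances`` its per-class beta blocks.
    """

    K: int
    labels: list
    class_betas: np.ndarray          # K x p
    shares: np.ndarray               # K
    posteriors: np.ndarray           # n_resp x K
    respondent_ids: list
    loglik: float
    loglik_trace: list
    n_obs: int
    n_params: int
    n_respondents: int
    n_starts: int
    best_start_seed: int
    converged: bool
    coding: CodingScheme
    covariance: np.ndarray | None = None
    class_covariances: list | None = None

    def class_se(self, k: int) -> np.ndarray:
        if self.class_covariances is None:
            raise EstimationError("covariance was not computed")
        return np.sqrt(np.clip(np.diag(self.class_covariances[k]), 0.0, None))

    @property
    def share_se(self) -> np.ndarray:
        """Delta-method standard errors of the class shares (from the
        share log-odds block of the full-mixture covariance)."""
        if self.covariance is None:
            raise EstimationError("covariance was not computed")
        K, p = self.K, len(self.labels)
        if K == 1:
            return np.zeros(1)
        cov_alpha = self.covariance[K * p:, K * p:]
        pi = self.shares
        # d pi_k / d alpha_m for m = 2..K (alpha_1 fixed at 0)
        J = np.array([[pi[k] * ((1.0 if k == m else 0.0) - pi[m])
                       for m in range(1, K)] for k in range(K)])
        var = np.diag(J @ cov_alpha @ J.T)
        return np.sqrt(np.clip(var, 0.0, None))

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "labels": list(self.labels),
            "class_betas": self.class_betas.tolist(),
            "shares": self.shares.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_respondents": self.n_respondents,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "indices": information_criteria(self),
        }


def information_criteria(fit: LatentClassFit) -> dict:
    """cAIC and adjusted BIC with n = number of respondents."""
    n, k, ll = fit.n_respondents, fit.n_params, fit.loglik
    return {
        "cAIC": -2.0 * ll + k * (np.log(n) + 1.0),
        "aBIC": -2.0 * ll + k * np.log((n + 2.0) / 24.0),
    }


def _e_step(L, shares):
    with np.errstate(divide="ignore"):
        logtau = L + np.log(shares)
    logtau -= logsumexp(logtau, axis=1, keepdims=True)
    tau = np.exp(logtau)
    ll = float(logsumexp(L + np.log(shares), axis=1).sum())
    return tau, ll


def _mixture_score(theta, K, p, X, y, groups, n_resp):
    """Analytic score of the mixture log-likelihood in theta =
    (beta_1..K flattened, share log-odds alpha_2..K, alpha_1 = 0)."""
    betas = theta[: K * p].reshape(K, p)
    alpha = np.concatenate([[0.0], theta[K * p:]])
    shares = np.exp(alpha - logsumexp(alpha))
    L = _respondent_class_loglik(X, y, groups, n_resp, betas)
    tau, _ = _e_step(L, shares)
    g = np.empty_like(theta)
    for k in range(K):
        resid = y - expit(X @ betas[k])          # d logP / d z
        w = tau[groups, k]
        g[k * p:(k + 1) * p] = X.T @ (w * resid)
    g[K * p:] = tau.sum(axis=0)[1:] - n_resp * shares[1:]
    return g


def _mixture_covariance(betas, shares, X, y, groups, n_resp):
    """Observed-information covariance by central FD of the score."""
    K, p = betas.shape
    alpha = np.log(shares) - np.log(shares[0])
    theta = np.concatenate([betas.ravel(), alpha[1:]])
    d = len(theta)
    H = np.zeros((d, d))
    for j in range(d):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        gp = _mixture_score(tp, K, p, X, y, groups, n_resp)
        gm = _mixture_score(tm, K, p, X, y, groups, n_resp)
        H[:, j] = (gp - gm) / (2.0 * h)
    H = 0.5 * (H + H.T)
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return cov


def em_fit(dataset: ChoiceDataset, plan: DesignPlan,
           coding: CodingScheme | None = None, K: int = 2,
           n_starts: int = 20, seed: int = 0, tol: float = 1e-7,
           max_iter: int = 500,
           compute_covariance: bool = True) -> LatentClassFit:
    """Fit a K-class mixture by EM, best of ``n_starts`` seeded starts.

    Each start initialises posteriors from a Dirichlet draw per
    respondent; iterations stop when the log-likelihood improves by
    less than ``tol``.  A start whose smallest class share falls below
    1/n_respondents is discarded as degenerate.  Classes of the best
    solution are sorted by descending share for stable labelling.
    """
    if K < 1:
        raise EstimationError("K must be >= 1")
    if coding is None:
        coding = default_coding(plan.schema)
    X, y, groups, uniq, labels = _stack(dataset, plan, coding)
    n_resp, p = len(uniq), X.shape[1]

    best = None
    best_seed = None
    for s in range(n_starts if K > 1 else 1):
        start_seed = seed + s
        rng = np.random.default_rng(start_seed)
        if K == 1:
            tau = np.ones((n_resp, 1))
        else:
            tau = rng.dirichlet(np.ones(K), size=n_resp)
        betas = np.zeros((K, p))
        shares = np.full(K, 1.0 / K)
        trace = []
        degenerate = False
        prev_ll = -np.inf
        for _ in range(max_iter):
            # M step
            shares = tau.mean(axis=0)
            if shares.min() < 1.0 / n_resp:
                degenerate = True
                break
            # generalized M step: warm-started Newton with step halving never
            # decreases the weighted likelihood, so EM stays monotone
            for k in range(K):
                w = tau[groups, k]
                betas[k], _, _ = newton_logit(X, y, weights=w,
                                              beta0=betas[k], gtol=1e-6,
                                              max_iter=25)
            # E step
            L = _respondent_class_loglik(X, y, groups, n_resp, betas)
            tau, ll = _e_step(L, shares)
            trace.append(ll)
            if ll - prev_ll < tol and np.isfinite(prev_ll):
                break
            prev_ll = ll
        if degenerate or not trace:
            continue
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], betas.copy(), shares.copy(), tau.copy(), trace)
            best_seed = start_seed

    if best is None:
        raise EstimationError(
            "all EM starts degenerated; reduce K or provide more data"
        )
    ll, betas, shares, tau, trace = best
    order = np.argsort(-shares)
    betas, shares, tau = betas[order], shares[order], tau[:, order]

    cov = class_covs = None
    if compute_covariance:
        cov = _mixture_covariance(betas, shares, X, y, groups, n_resp)
        class_covs = [cov[k * p:(k + 1) * p, k * p:(k + 1) * p]
                      for k in range(K)]

    return LatentClassFit(
        K=K, labels=list(labels), class_betas=betas, shares=shares,
        posteriors=tau, respondent_ids=list(uniq), loglik=ll,
        loglik_trace=list(trace), n_obs=len(y),
        n_params=K * p + (K - 1), n_respondents=n_resp,
        n_starts=n_starts, best_start_seed=int(best_seed), converged=True,
        coding=coding, covariance=cov, class_covariances=class_covs,
    )


@dataclass
class ModelSelection:
    chosen_K: int
    table: pd.DataFrame


def model_selection(fits) -> ModelSelection:
    """Choose K by consistent AIC (ties favour the smaller K).

    ``fits`` maps K -> :class:`LatentClassFit` on identical data; the
    table reports log-likelihood, cAIC and aBIC for every K.
    """
    rows = []
    for K in sorted(fits):
        f = fits[K]
        idx = information_criteria(f)
        rows.append({"K": K, "loglik": f.loglik, "n_params": f.n_params,
                     "cAIC": idx["cAIC"], "aBIC": idx["aBIC"]})
    table = pd.DataFrame(rows)
    chosen = None
    best = np.inf
    for row in rows:
        if row["cAIC"] < best:  # strict: ties keep the smaller K
            best = row["cAIC"]
            chosen = row["K"]
    return ModelSelection(chosen, table)


def assign_classes(fit: LatentClassFit) -> pd.Series:
    """Hard assignment: each respondent's highest-posterior class
    (0-based; ties go to the lower index)."""
    assignment = np.argmax(fit.posteriors, axis=1)
    return pd.Series(assignment, index=fit.respondent_ids, name="class")


@dataclass
class MembershipResult:
    univariate: pd.DataFrame
    multivariable: pd.DataFrame
    eligible: list


def _logistic_table(Xm, y, names):
    beta, converged, message = newton_logit(Xm, y)
    H = information(beta, Xm, y)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    from scipy.stats import norm

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * norm.sf(np.abs(z))
    return pd.DataFrame({
        "term": names, "coef": beta, "se": se,
        "odds_ratio": np.exp(beta), "p": pvals,
        "converged": converged,
    })


def membership_logistic(assignments: pd.Series, covariates: pd.DataFrame,
                        variables, a_priori=("age", "prior_cancellation"),
                        multivariable=None,
                        screen_p: float = 0.15) -> MembershipResult:
    """Relate hard class membership (K=2) to respondent covariates.

    Fits a univariate logistic regression per variable (outcome:
    membership in class 2, the smaller class).  Variables named in
    ``a_priori`` are always eligible for the multivariable model;
    any other variable becomes eligible only when its univariate p-value
    is below ``screen_p``.  The multivariable model is limited to two
    variables to avoid overfitting on a small sample and defaults to the
    a-priori pair.
    """
    vals = set(pd.unique(assignments))
    if not vals <= {0, 1}:
        raise EstimationError("membership model requires a two-class fit")
    cov = covariates.set_index("respondent_id").loc[assignments.index]
    y = assignments.to_numpy(dtype=float)

    def column(name):
        if name not in cov.columns:
            raise EstimationError(f"unknown covariate {name!r}")
        s = cov[name]
        if not pd.api.types.is_numeric_dtype(s):
            raise EstimationError(
                f"covariate {name!r} is not numeric; dummy-code it first"
            )
        return s.to_numpy(dtype=float)

    uni_rows = []
    pvalues = {}
    for v in dict.fromkeys(list(a_priori) + list(variables)):
        Xm = np.column_stack([np.ones(len(y)), column(v)])
        tab = _logistic_table(Xm, y, ["intercept", v])
        row = tab.iloc[1].to_dict()
        row["variable"] = v
        pvalues[v] = row["p"]
        uni_rows.append(row)
    univariate = pd.DataFrame(uni_rows)[
        ["variable", "coef", "se", "odds_ratio", "p", "converged"]
    ]

    eligible = [v for v in dict.fromkeys(list(a_priori) + list(variables))
                if v in a_priori or pvalues[v] < screen_p]

    if multivariable is None:
        multivariable = list(a_priori)[:2]
    multivariable = list(multivariable)
    if len(multivariable) > 2:
        raise EstimationError(
            "multivariable membership models are limited to two variables"
        )
    for v in multivariable:
        if v not in eligible:
            raise EstimationError(
                f"{v!r} is not eligible: not pre-specified and univariate "
                f"p >= {screen_p}"
            )
    Xm = np.column_stack([np.ones(len(y))] + [column(v) for v in multivariable])
    multi = _logistic_table(Xm, y, ["intercept"] + multivariable)
    return MembershipResult(univariate, multi, eligible)


def format_lc_table(fit: LatentClassFit, overall: MNLFit | None = None) -> str:
    """Report per-class coefficients beside the pooled model."""
    idx = information_criteria(fit)
    header = ["term".ljust(18)]
    if overall is not None:
        header.append("overall".rjust(10))
    header += [f"class {k + 1} ({100 * s:.0f}%)".rjust(18)
               for k, s in enumerate(fit.shares)]
    lines = ["Latent-class conditional logit", "-" * 31, "".join(header)]
    for j, lab in enumerate(fit.labels):
        row = [lab.ljust(18)]
        if overall is not None:
            row.append(f"{overall.beta[j]:>10.3f}")
        row += [f"{fit.class_betas[k, j]:>18.3f}" for k in range(fit.K)]
        lines.append("".join(row))
    lines.append(f"log-likelihood {fit.loglik:.1f}   cAIC {idx['cAIC']:.1f}   "
                 f"aBIC {idx['aBIC']:.1f}   n={fit.n_respondents} respondents")
    return "\n".join(lines)
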