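"""Conditional logit estimation for paired stated choices.

With exactly two unlabeled alternatives per question, the conditional
(multinomial) logit reduces to a binary logit on attribute differences:
the probability of choosing alternative A in a set is

    P(A) = logistic( (x_A - x_B)' beta  [+ c] )

where x are the coded attribute values and c an optional position
constant for alternative A.  This module provides the coding scheme
(continuous in stated units vs reference-level dummies), the reduction
of a :class:`~ohsspref.data.ChoiceDataset` to the difference design
matrix, an analytic-Hessian Newton maximum-likelihood fit with Wald
intervals, fit indices (AIC, consistent AIC, McFadden pseudo R²), and
an AIC-based continuous-vs-categorical coding selection mirroring the
usual linearity check for multi-level quantitative attributes.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass

import numpy as np

from .data import ChoiceDataset
from .design import DesignPlan, Profile

__all__ = [
    "AttributeCoding",
    "CodingScheme",
    "MNLFit",
    "EstimationError",
    "default_coding",
    "coded_labels",
    "code_values",
    "code_profile",
    "build_difference_matrix",
    "negloglik",
    "score",
    "information",
    "fit_mnl",
    "fit_indices",
    "select_coding",
    "format_fit_table",
]


class EstimationError(ValueError):
    """Model cannot be estimated on the given data."""


@dataclass(frozen=True)
class AttributeCoding:
    """Coding of one attribute: ``continuous`` (value / scale) or
    ``categorical`` (dummies against the reference level)."""

    kind: str
    scale: float = 1.0
    reference: object = None

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise EstimationError(f"unknown coding kind {self.kind!r}")


@dataclass(frozen=True)
class CodingScheme:
    """Per-attribute coding plus an optional A-position constant."""

    per_attribute: dict
    include_position_constant: bool = False

    def coding_for(self, name: str) -> AttributeCoding:
        try:
            return self.per_attribute[name]
        except KeyError:
            raise EstimationError(f"no coding for attribute {name!r}")

    def with_attribute(self, name: str, coding: AttributeCoding):
        d = dict(self.per_attribute)
        d[name] = coding
        return CodingScheme(d, self.include_position_constant)


def default_coding(schema, include_position_constant: bool = False
                   ) -> CodingScheme:
    """Coding scheme from each attribute's ``coding_default``.

    Continuous attributes are scaled by their ``continuous_scale`` so
    coefficients are in the stated units (per 1% OHSS, per €1000, ...);
    categorical attributes use the first (best) level as reference.
    """
    per = {}
    for a in schema:
        if a.coding_default == "continuous":
            per[a.name] = AttributeCoding("continuous", scale=a.continuous_scale)
        else:
            per[a.name] = AttributeCoding("categorical", reference=a.levels[0])
    return CodingScheme(per, include_position_constant)


def coded_labels(schema, coding: CodingScheme, with_constant: bool = False):
    """Column labels of the coded design, schema order; categorical
    attributes contribute one ``name:level`` label per non-reference level."""
    labels = []
    for a in schema:
        c = coding.coding_for(a.name)
        if c.kind == "continuous":
            labels.append(a.name)
        else:
            ref = a.levels[0] if c.reference is None else c.reference
            labels.extend(f"{a.name}:{lv}" for lv in a.levels if lv != ref)
    if with_constant and coding.include_position_constant:
        labels.append("const")
    return labels


def code_values(values: dict, schema, coding: CodingScheme) -> np.ndarray:
    """Code a dict of raw attribute values into a design row (no constant)."""
    out = []
    for a in schema:
        c = coding.coding_for(a.name)
        v = values[a.name]
        if c.kind == "continuous":
            out.append(float(v) / c.scale)
        else:
            ref = a.levels[0] if c.reference is None else c.reference
            for lv in a.levels:
                if lv != ref:
                    out.append(1.0 if v == lv else 0.0)
    return np.asarray(out)


def code_profile(profile: Profile, schema, coding: CodingScheme) -> np.ndarray:
    return code_values(profile.values(schema), schema, coding)


def beta_from_dict(beta: dict, schema, coding: CodingScheme,
                   with_constant: bool = False) -> np.ndarray:
    """Order a label->value coefficient dict into the coded layout."""
    labels = coded_labels(schema, coding, with_constant)
    try:
        return np.array([float(beta[l]) for l in labels])
    except KeyError as e:
        raise EstimationError(f"missing coefficient for {e.args[0]!r}")


DiffData = namedtuple("DiffData", ["X", "y", "respondent_ids", "labels"])


def build_difference_matrix(dataset: ChoiceDataset, plan: DesignPlan,
                            coding: CodingScheme,
                            include_dominance: bool = False) -> DiffData:
    """Reduce paired choices to the binary-logit difference design.

    One row per answered respondent x estimation set: coded(A) minus
    coded(B), plus a constant column when the coding includes the
    position constant; ``y`` is 1 when A was chosen.  Dominance sets
    are excluded unless ``include_dominance`` (they screen respondents
    and would otherwise distort the coefficients).  A set with a
    missing alternative or no recorded choice should have been excluded
    upstream and raises.
    """
    use = {cs.id: cs for cs in plan.choice_sets
           if include_dominance or not cs.is_dominance_test}
    rec = dataset.records
    rec = rec.loc[rec["choice_set_id"].isin(use)]
    diff_by_set = {}
    for sid, cs in use.items():
        da = code_profile(cs.a, plan.schema, coding)
        db = code_profile(cs.b, plan.schema, coding)
        diff_by_set[sid] = da - db
    chosen = rec.loc[rec["chosen"] == 1]
    counts = rec.groupby(["respondent_id", "choice_set_id"]).size()
    if (counts != 2).any():
        rid, sid = counts[counts != 2].index[0]
        raise EstimationError(
            f"respondent {rid} set {sid}: expected two alternatives; "
            "exclude incomplete respondents upstream"
        )
    n_sets = rec.groupby("respondent_id")["choice_set_id"].nunique()
    if len(n_sets) and (n_sets != len(use)).any():
        rid = n_sets[n_sets != len(use)].index[0]
        raise EstimationError(
            f"respondent {rid}: unanswered choice sets; exclude incomplete "
            "respondents upstream"
        )
    per_set = chosen.groupby(["respondent_id", "choice_set_id"]).size()
    if (per_set != 1).any():
        rid, sid = per_set[per_set != 1].index[0]
        raise EstimationError(f"respondent {rid} set {sid}: no unique choice")
    set_ids = list(use)
    pos = {s: i for i, s in enumerate(set_ids)}
    diff = np.array([diff_by_set[s] for s in set_ids])
    if len(chosen):
        X = diff[chosen["choice_set_id"].map(pos).to_numpy()]
        y = (chosen["alternative"] == "A").to_numpy(dtype=float)
        rids = chosen["respondent_id"].to_numpy()
    else:
        X = np.empty((0, len(coded_labels(plan.schema, coding))))
        y = np.empty(0)
        rids = np.empty(0)
    if coding.include_position_constant:
        X = np.column_stack([X, np.ones(len(X))])
    return DiffData(X, y, rids,
                    coded_labels(plan.schema, coding, with_constant=True))


# ---------------------------------------------------------------------------
# likelihood

def _check_finite(*arrays):
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise EstimationError("non-finite values in likelihood inputs")


def negloglik(beta, X, y, weights=None) -> float:
    """Binary-logit negative log-likelihood (optionally row-weighted)."""
    beta = np.asarray(beta, dtype=float)
    _check_finite(beta, X, y)
    z = X @ beta
    # softplus(z) - y z, numerically stable
    ll_terms = np.logaddexp(0.0, z) - y * z
    if weights is not None:
        ll_terms = weights * ll_terms
    return float(ll_terms.sum())


def score(beta, X, y, weights=None) -> np.ndarray:
    """Gradient of :func:`negloglik` with respect to ``beta``."""
    from scipy.special import expit

    beta = np.asarray(beta, dtype=float)
    _check_finite(beta, X, y)
    resid = expit(X @ beta) - y
    if weights is not None:
        resid = weights * resid
    return X.T @ resid


def information(beta, X, y=None, weights=None) -> np.ndarray:
    """Observed information X' W X with W = w p(1-p)."""
    from scipy.special import expit

    beta = np.asarray(beta, dtype=float)
    _check_finite(beta, X)
    p = expit(X @ beta)
    w = p * (1.0 - p)
    if weights is not None:
        w = weights * w
    return (X * w[:, None]).T @ X


def newton_logit(X, y, weights=None, beta0=None, gtol: float = 1e-8,
                 max_iter: int = 200, separation_bound: float = 50.0):
    """Newton-Raphson with step halving for the (weighted) binary logit.

    Returns ``(beta, converged, message)``.  Separation (a coefficient
    running away) is flagged, not silently accepted.
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    if n == 0:
        raise EstimationError("no observations")
    if np.linalg.matrix_rank(X) < p:
        raise EstimationError("design matrix is rank deficient")
    nll = negloglik(beta, X, y, weights)
    converged, message = False, "max iterations reached"
    for _ in range(max_iter):
        g = score(beta, X, y, weights)
        if np.max(np.abs(g)) < gtol:
            converged, message = True, "gradient tolerance reached"
            break
        H = information(beta, X, y, weights)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            cand = beta - t * step
            cand_nll = negloglik(cand, X, y, weights)
            if cand_nll <= nll:
                break
            t /= 2.0
        beta, nll = beta - t * step, cand_nll
        if np.max(np.abs(beta)) > separation_bound:
            converged = False
            message = "separation suspected (coefficient diverging)"
            break
    return beta, converged, message


@dataclass
class MNLFit:
    """A fitted conditional logit: estimates, covariance and indices."""

    labels: list
    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    null_loglik: float
    n_obs: int
    n_params: int
    converged: bool
    coding: CodingScheme
    message: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    @property
    def ci95(self) -> np.ndarray:
        half = 1.96 * self.se
        return np.column_stack([self.beta - half, self.beta + half])

    def coef(self, label: str) -> float:
        return float(self.beta[self.labels.index(label)])

    def to_dict(self) -> dict:
        idx = fit_indices(self)
        return {
            "labels": list(self.labels),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "ci95": self.ci95.tolist(),
            "covariance": self.covariance.tolist(),
            "loglik": self.loglik,
            "null_loglik": self.null_loglik,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "indices": idx,
        }


def fit_mnl(dataset: ChoiceDataset, plan: DesignPlan,
            coding: CodingScheme | None = None, gtol: float = 1e-8,
            max_iter: int = 200) -> MNLFit:
    """Maximum-likelihood conditional logit on the difference design.

    Deterministic given the data; covariance is the inverse observed
    information at the optimum.
    """
    if coding is None:
        coding = default_coding(plan.schema)
    X, y, _, labels = build_difference_matrix(dataset, plan, coding)
    beta, converged, message = newton_logit(X, y, gtol=gtol, max_iter=max_iter)
    H = information(beta, X, y)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    n = len(y)
    return MNLFit(
        labels=list(labels), beta=beta, covariance=cov,
        loglik=-negloglik(beta, X, y), null_loglik=-n * np.log(2.0),
        n_obs=n, n_params=X.shape[1], converged=converged, coding=coding,
        message=message,
    )


def fit_indices(fit: MNLFit) -> dict:
    """AIC, consistent AIC and McFadden pseudo R².

    The null model is the equal-probability choice (log-likelihood
    ``-n log 2``), natural for unlabeled paired alternatives.
    """
    ll, k, n = fit.loglik, fit.n_params, fit.n_obs
    return {
        "AIC": -2.0 * ll + 2.0 * k,
        "cAIC": -2.0 * ll + k * (np.log(n) + 1.0),
        "pseudo_r2": 1.0 - ll / fit.null_loglik,
    }


@dataclass
class CodingSelection:
    """Outcome of the linearity check for one attribute."""

    attribute: str
    chosen: str
    aic_continuous: float
    aic_categorical: float
    level_coefficients: dict


def select_coding(dataset: ChoiceDataset, plan: DesignPlan, attribute: str,
                  coding: CodingScheme | None = None,
                  tolerance: float = 0.0) -> CodingSelection:
    """Choose continuous vs categorical coding for one attribute by AIC.

    Both codings are fitted with all other attributes at the given (or
    default) coding; continuous wins when its AIC is within
    ``tolerance`` of the categorical AIC (parsimony).  The per-level
    categorical coefficients are reported so the linearity of the level
    effects can also be inspected directly.  A two-level attribute is
    returned as continuous by convention (the codings are equivalent).
    """
    if coding is None:
        coding = default_coding(plan.schema)
    attr = plan.attribute(attribute)
    fits = {}
    for kind in ("continuous", "categorical"):
        c = (AttributeCoding("continuous", scale=attr.continuous_scale)
             if kind == "continuous"
             else AttributeCoding("categorical", reference=attr.levels[0]))
        fits[kind] = fit_mnl(dataset, plan, coding.with_attribute(attribute, c))
    aic_cont = fit_indices(fits["continuous"])["AIC"]
    aic_cat = fit_indices(fits["categorical"])["AIC"]
    level_coefs = {
        lab.split(":", 1)[1]: fits["categorical"].coef(lab)
        for lab in fits["categorical"].labels
        if lab.startswith(f"{attribute}:")
    }
    if attr.n_levels == 2:
        chosen = "continuous"
    else:
        chosen = "continuous" if aic_cont <= aic_cat + tolerance else "categorical"
    return CodingSelection(attribute, chosen, aic_cont, aic_cat, level_coefs)


def format_fit_table(fit: MNLFit, title: str = "Conditional logit") -> str:
    """Human-readable coefficient table with 95% CIs and fit indices."""
    idx = fit_indices(fit)
    lines = [title, "-" * len(title),
             f"{'term':<18}{'coef':>10}{'95% CI':>24}"]
    for lab, b, (lo, hi) in zip(fit.labels, fit.beta, fit.ci95):
        lines.append(f"{lab:<18}{b:>10.3f}{f'{lo:.3f} to {hi:.3f}':>24}")
    lines.append(f"log-likelihood  {fit.loglik:.1f}   (null {fit.null_loglik:.1f})")
    lines.append(
        f"pseudo R2 {idx['pseudo_r2']:.3f}   AIC {idx['AIC']:.1f}   "
        f"cAIC {idx['cAIC']:.1f}   n={fit.n_obs}"
    )
    if not fit.converged:
        lines.append(f"WARNING: not converged ({fit.message})")
    return "\n".join(lines)
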