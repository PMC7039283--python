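"""Willingness-to-trade estimation: marginal rates of substitution.

The numeraire is the chance of OHSS, modelled continuously per
percentage point, so each trade-off answers: how many percentage points
of OHSS risk reduction offset a stated worsening of another attribute
(5 points more cancellation risk, one extra treatment to pregnancy,
4 or 20 injections instead of none, €1000 instead of no cost)?  The
point estimate is the ratio of utility changes

    MRS = |delta V(attribute change)| / |beta_OHSS per 1%|,

invariant to the common utility scale.  Uncertainty follows the
Krinsky-Robb approach: coefficients are drawn from their asymptotic
multivariate normal sampling distribution and the median and 2.5/97.5
percentiles of the per-draw ratios are reported.  For a latent-class
fit, a class-probability-weighted variant pools draws across classes,
sampling a class per draw with its estimated share.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass

import numpy as np

from .latent import LatentClassFit
from .mnl import EstimationError, MNLFit

__all__ = [
    "LevelChange",
    "MRSEstimate",
    "standard_changes",
    "importance_change",
    "mrs_point",
    "krinsky_robb_draws",
    "mrs_interval",
    "class_weighted_mrs",
    "format_mrs_table",
]

LevelChange = namedtuple("LevelChange", ["attribute", "from_level", "to_level"])


def standard_changes(schema) -> list:
    """The canonical trade-offs reported for the OHSS instrument."""
    by_name = {a.name: a for a in schema}
    out = []
    if "cancellation" in by_name:
        out.append(("cancellation 5% more", LevelChange("cancellation", 0, 5)))
    if "pregnancy" in by_name:
        out.append(("one treatment extra", LevelChange("pregnancy", 1, 2)))
    if "injections" in by_name:
        out.append(("4 versus 0 injections", LevelChange("injections", 0, 4)))
        out.append(("20 versus 0 injections", LevelChange("injections", 0, 20)))
    if "cost" in by_name:
        out.append(("€1000 versus no costs", LevelChange("cost", 0, 1000)))
    return out


@dataclass
class MRSEstimate:
    """A trade-off ratio in percentage points of OHSS chance."""

    description: str
    point: float
    median: float
    ci95: tuple
    n_draws: int
    seed: int
    weighting: str = "overall"
    n_degenerate: int = 0

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.median <= hi):
            raise ValueError("interval must bracket the median")

    def to_dict(self) -> dict:
        return {
            "description": self.description, "point": self.point,
            "median": self.median, "ci95": list(self.ci95),
            "n_draws": self.n_draws, "seed": self.seed,
            "weighting": self.weighting, "n_degenerate": self.n_degenerate,
        }


def _delta_vector(labels, coding, attribute, from_level, to_level):
    """Linear functional d such that d' beta = delta utility."""
    d = np.zeros(len(labels))
    c = coding.coding_for(attribute)
    if c.kind == "continuous":
        if attribute not in labels:
            raise EstimationError(f"{attribute!r} missing from the fit")
        d[labels.index(attribute)] = (to_level - from_level) / c.scale
    else:
        for level, sign in ((to_level, 1.0), (from_level, -1.0)):
            if level == c.reference:
                continue
            lab = f"{attribute}:{level}"
            if lab not in labels:
                raise EstimationError(
                    f"level {level!r} not valid for attribute {attribute!r}"
                )
            d[labels.index(lab)] += sign
    return d


def importance_change(fit: MNLFit, attribute: str, from_level,
                      to_level) -> float:
    """Utility change for moving one attribute between two levels.

    Continuous coding: ``beta * (to - from)`` in the coefficient's
    units; categorical coding: ``beta_to - beta_from`` with the
    reference level at zero.
    """
    d = _delta_vector(fit.labels, fit.coding, attribute, from_level, to_level)
    return float(d @ fit.beta)


def _ratio(du, b_ohss):
    return np.abs(du) / np.abs(b_ohss)


def _ohss_index(fit, numeraire):
    c = fit.coding.coding_for(numeraire)
    if c.kind != "continuous":
        raise EstimationError(
            f"numeraire {numeraire!r} must be modelled continuously"
        )
    return fit.labels.index(numeraire)


def mrs_point(fit: MNLFit, change: LevelChange,
              numeraire: str = "ohss") -> float:
    """Point MRS: |delta utility| / |per-1% OHSS coefficient|.

    Positive values are the OHSS-risk reduction (percentage points)
    required to accept the stated worsening.
    """
    j = _ohss_index(fit, numeraire)
    b = fit.beta[j]
    if b == 0.0:
        raise EstimationError("numeraire coefficient is zero; MRS undefined")
    du = importance_change(fit, *change)
    return float(_ratio(du, b))


def krinsky_robb_draws(fit: MNLFit, n_draws: int = 10000,
                       seed: int = 0) -> np.ndarray:
    """Draw coefficient vectors from N(beta_hat, Sigma_hat).

    Slightly negative covariance eigenvalues (numerical noise) are
    floored at 1e-12 with a warning; a substantively non-PSD matrix is
    an error.  Deterministic given ``seed``.
    """
    cov = np.asarray(fit.covariance, dtype=float)
    cov = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(cov)
    scale = max(1.0, float(np.abs(vals).max()))
    if vals.min() < -1e-8 * scale:
        raise EstimationError("covariance is not positive semi-definite")
    if vals.min() < 0.0:
        warnings.warn("flooring slightly negative covariance eigenvalues")
        vals = np.clip(vals, 1e-12, None)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, len(vals)))
    return fit.beta + z * np.sqrt(vals) @ vecs.T


def _draws_to_estimate(description, point, ratios, n_requested, seed,
                       weighting):
    n_degenerate = n_requested - len(ratios)
    if len(ratios) == 0:
        raise EstimationError("all draws degenerate; no MRS distribution")
    if n_degenerate > 0.10 * n_requested:
        warnings.warn(
            f"{n_degenerate}/{n_requested} draws had a near-zero numeraire "
            "coefficient and were dropped"
        )
    lo, med, hi = np.percentile(ratios, [2.5, 50.0, 97.5])
    return MRSEstimate(description, point, float(med), (float(lo), float(hi)),
                       n_requested, seed, weighting, int(n_degenerate))


def mrs_interval(fit: MNLFit, change: LevelChange, n_draws: int = 10000,
                 seed: int = 0, numeraire: str = "ohss",
                 description: str | None = None) -> MRSEstimate:
    """Krinsky-Robb median and 95% percentile interval for one MRS.

    Draws with a numeraire coefficient smaller than 1e-8 in magnitude
    are dropped and counted (a warning is raised past 10%).
    """
    point = mrs_point(fit, change, numeraire)
    draws = krinsky_robb_draws(fit, n_draws, seed)
    j = _ohss_index(fit, numeraire)
    d = _delta_vector(fit.labels, fit.coding, *change)
    du = draws @ d
    b = draws[:, j]
    keep = np.abs(b) >= 1e-8
    ratios = _ratio(du[keep], b[keep])
    if description is None:
        description = f"{change.attribute} {change.from_level}->{change.to_level}"
    return _draws_to_estimate(description, point, ratios, n_draws, seed,
                              "overall")


def class_weighted_mrs(lc_fit: LatentClassFit, change: LevelChange,
                       n_draws: int = 10000, seed: int = 0,
                       numeraire: str = "ohss",
                       description: str | None = None) -> MRSEstimate:
    """Class-probability-weighted Krinsky-Robb MRS from a latent-class fit.

    For each draw a class is sampled with its estimated share and a
    coefficient vector is drawn from that class's sampling
    distribution; the pooled ratio draws yield an "overall" trade-off
    acknowledging preference heterogeneity.  The point estimate is the
    share-weighted mean of the per-class point ratios.
    """
    if lc_fit.K < 2:
        raise EstimationError("class-weighted MRS needs K >= 2")
    labels = list(lc_fit.labels)
    coding = lc_fit.coding
    d = _delta_vector(labels, coding, *change)
    c = coding.coding_for(numeraire)
    if c.kind != "continuous":
        raise EstimationError(
            f"numeraire {numeraire!r} must be modelled continuously"
        )
    j = labels.index(numeraire)

    point = 0.0
    for k in range(lc_fit.K):
        b = lc_fit.class_betas[k]
        if b[j] == 0.0:
            raise EstimationError("numeraire coefficient is zero in a class")
        point += lc_fit.shares[k] * float(_ratio(d @ b, b[j]))

    rng = np.random.default_rng(seed)
    classes = rng.choice(lc_fit.K, size=n_draws, p=lc_fit.shares)
    ratios = []
    for k in range(lc_fit.K):
        n_k = int((classes == k).sum())
        if n_k == 0:
            continue
        cov = (lc_fit.class_covariances[k]
               if lc_fit.class_covariances is not None
               else np.zeros((len(labels), len(labels))))
        sub = MNLFit(labels=labels, beta=lc_fit.class_betas[k],
                     covariance=cov, loglik=np.nan, null_loglik=np.nan,
                     n_obs=lc_fit.n_obs, n_params=len(labels),
                     converged=lc_fit.converged, coding=coding)
        draws = krinsky_robb_draws(sub, n_k, seed=seed + 1 + k)
        du = draws @ d
        b = draws[:, j]
        keep = np.abs(b) >= 1e-8
        ratios.append(_ratio(du[keep], b[keep]))
    ratios = np.concatenate(ratios)
    if description is None:
        description = f"{change.attribute} {change.from_level}->{change.to_level}"
    return _draws_to_estimate(description, point, ratios, n_draws, seed,
                              "class-weighted")


def format_mrs_table(estimates) -> str:
    """Render trade-offs as '% decrease in OHSS chance to accept the
    undesirable attribute' with 95% intervals."""
    lines = [
        "% decrease in chance of OHSS to accept the undesirable attribute",
        "-" * 64,
        f"{'change':<28}{'MRS':>8}{'95% CI':>20}",
    ]
    for est in estimates:
        lo, hi = est.ci95
        lines.append(
            f"{est.description:<28}{est.median:>8.1f}"
            f"{f'({lo:.1f}-{hi:.1f})':>20}"
        )
    return "\n".join(lines)
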