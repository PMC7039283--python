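"""Synthetic respondents and stated choices under a random-utility model.

Every downstream stage of the pipeline (exclusions, conditional logit,
latent-class analysis, trade-off estimation) is testable against a
known ground truth by simulating the questionnaire round: respondents
are drawn with covariates matching the study cohort, assigned to a
latent preference class, and answer each binary choice set with the
logit probability implied by their class's linear utility (Gumbel
errors with scale fixed to 1, the standard logit identification, so
coefficients are interpreted on the reported scale directly).

Field realism knobs mirror a postal questionnaire: a response rate,
incomplete questionnaires, and "careless" respondents who answer
uniformly at random on every set — a single mechanism that also
explains dominance-test failures without special-casing them.

The reference population bundled here uses, as its ground truth, the
fitted two-class preference structure reported for women at increased
OHSS risk (class shares 46%/54%) and the cohort's covariate
prevalences; :func:`overall_reference_beta` carries the corresponding
pooled single-class coefficients.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import ChoiceDataset
from .design import (ChoiceSet, DesignPlan, Profile, build_design,
                     default_schema, is_dominant)
from .mnl import CodingScheme, beta_from_dict, code_profile, default_coding

__all__ = [
    "PopulationModel",
    "SimulationConfig",
    "ConfigError",
    "overall_reference_beta",
    "reference_population",
    "single_class_population",
    "default_covariate_model",
    "study_cascade_config",
    "draw_respondents",
    "systematic_utility",
    "choice_probability",
    "simulate_dataset",
    "simulate_study",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def overall_reference_beta() -> dict:
    """Pooled (single-class) reference coefficients, by coded label.

    Units: per 1% OHSS chance, per 1% cancellation chance, per extra
    treatment to a 30% pregnancy chance, injection dummies against 0
    injections, per €1000 cost.  All negative: lower levels of every
    attribute are preferred.
    """
    return {
        "ohss": -0.22,
        "injections:4": -0.52,
        "injections:20": -0.93,
        "pregnancy": -0.84,
        "cancellation": -0.086,
        "cost": -1.16,
    }


def class_reference_betas() -> tuple:
    """Two-class reference coefficients (class 1: pregnancy-driven, 46%;
    class 2: safety- and cost-driven, 54%)."""
    class1 = {
        "ohss": -0.075,
        "injections:4": -0.31,
        "injections:20": -0.55,
        "pregnancy": -1.41,
        "cancellation": -0.19,
        "cost": -0.67,
    }
    class2 = {
        "ohss": -0.36,
        "injections:4": -0.87,
        "injections:20": -1.50,
        "pregnancy": -0.55,
        "cancellation": -0.051,
        "cost": -1.63,
    }
    return (class1, class2)


def default_covariate_model() -> dict:
    """Independent marginal distributions matching the cohort profile.

    Age is discrete uniform over the observed 21-39 range; binary flags
    use the reported prevalences (e.g. a previous cancelled cycle in
    37.4%, pregnant while answering in 12.1%); education, income and
    current treatment are categorical with the reported shares.  No
    covariance structure between covariates is imposed (none reported).
    """
    return {
        "age": ("duniform", 21, 39),
        "prior_cancellation": ("bernoulli", 0.374),
        "prior_ohss": ("bernoulli", 0.604),
        "pregnant": ("bernoulli", 0.121),
        "education": ("categorical",
                      {"low": 0.110, "moderate": 0.440, "high": 0.450}),
        "income": ("categorical",
                   {"low": 0.385, "moderate": 0.473, "high": 0.110,
                    "not_reported": 0.032}),
        "current_treatment": ("categorical", {"oi_iui": 0.549, "ivf": 0.451}),
    }


@dataclass(frozen=True)
class PopulationModel:
    """A mixture of linear random-utility classes plus covariates.

    ``class_betas`` are label->coefficient dicts on the coded scale of
    ``coding``; ``class_shares`` is the mixing distribution pi.  If
    ``membership_link`` is given (per non-baseline class: an intercept
    and label->coefficient dict over covariates), class membership is
    drawn from a multinomial logit on the covariates instead of pi.
    """

    class_shares: tuple
    class_betas: tuple
    covariate_model: dict = field(default_factory=default_covariate_model)
    membership_link: tuple | None = None

    def __post_init__(self):
        shares = np.asarray(self.class_shares, dtype=float)
        if len(shares) != len(self.class_betas):
            raise ConfigError("one beta vector per class required")
        if np.any(shares <= 0) or np.any(shares > 1):
            raise ConfigError("class shares must be in (0, 1]")
        if abs(shares.sum() - 1.0) > 1e-12:
            raise ConfigError("class shares must sum to 1")
        keys = set(self.class_betas[0])
        if any(set(b) != keys for b in self.class_betas):
            raise ConfigError("all class beta vectors must share labels")

    @property
    def n_classes(self) -> int:
        return len(self.class_shares)

    def to_dict(self) -> dict:
        return {
            "class_shares": list(self.class_shares),
            "class_betas": [dict(b) for b in self.class_betas],
        }


def reference_population() -> PopulationModel:
    """The two-class reference population (shares 0.46 / 0.54)."""
    return PopulationModel((0.46, 0.54), class_reference_betas())


def single_class_population(beta: dict | None = None) -> PopulationModel:
    """Degenerate one-class population, default the pooled reference."""
    if beta is None:
        beta = overall_reference_beta()
    return PopulationModel((1.0,), (beta,))


@dataclass(frozen=True)
class SimulationConfig:
    """Questionnaire-round configuration.

    Defaults emulate the study conditions: 120 invited, a 95/120
    response rate, 3/95 incomplete questionnaires, and a small careless
    rate chosen so that about one respondent in the cohort fails a
    dominance test (a uniformly random answerer fails at least one of
    two dominance sets with probability 3/4).  With ``exact_counts``
    the nonresponse/incompleteness counts are deterministic (rounded
    expectations), attentive respondents always pass the dominance
    tests, and ``forced_dominance_failures`` complete, non-careless
    respondents are forced to pick the dominated
    alternative on the first dominance set, reproducing the exclusion
    cascade exactly.
    """

    n_invited: int = 120
    response_rate: float = 95.0 / 120.0
    incomplete_rate: float = 3.0 / 95.0
    careless_rate: float = 0.015
    seed: int = 0
    exact_counts: bool = False
    forced_dominance_failures: int = 0

    def __post_init__(self):
        if self.n_invited < 1:
            raise ConfigError("n_invited must be >= 1")
        for name in ("response_rate", "incomplete_rate", "careless_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")


def study_cascade_config(seed: int = 0) -> SimulationConfig:
    """Deterministic fixture reproducing the 120→95→92→91 cascade."""
    return SimulationConfig(exact_counts=True, careless_rate=0.0,
                            forced_dominance_failures=1, seed=seed)


def _draw_covariate(rng, spec, n):
    kind = spec[0]
    if kind == "duniform":
        _, lo, hi = spec
        return rng.integers(lo, hi + 1, size=n)
    if kind == "bernoulli":
        _, p = spec
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"bernoulli prevalence {p} outside [0, 1]")
        return (rng.random(n) < p).astype(int)
    if kind == "categorical":
        _, table = spec
        labels = list(table)
        probs = np.asarray([table[k] for k in labels], dtype=float)
        if np.any(probs < 0) or probs.sum() <= 0:
            raise ConfigError("invalid categorical probabilities")
        probs = probs / probs.sum()
        return rng.choice(labels, size=n, p=probs)
    raise ConfigError(f"unknown covariate distribution {kind!r}")


def draw_respondents(n: int, pop_model: PopulationModel,
                     seed: int = 0) -> pd.DataFrame:
    """Draw ``n`` respondents: covariates i.i.d. from the covariate
    model and a latent class from the mixing shares (or the covariate
    link when given).

    The true class is stored as ``class_true`` for recovery scoring; it
    is a simulation bookkeeping column, never observable in a real
    study, and is excluded from covariate summaries.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {"respondent_id": [f"r{i + 1:04d}" for i in range(n)]}
    for name, spec in pop_model.covariate_model.items():
        cols[name] = _draw_covariate(rng, spec, n)
    df = pd.DataFrame(cols)
    K = pop_model.n_classes
    if pop_model.membership_link is None:
        classes = rng.choice(K, size=n, p=np.asarray(pop_model.class_shares))
    else:
        eta = np.zeros((n, K))
        for k, (intercept, coefs) in enumerate(pop_model.membership_link,
                                               start=1):
            eta[:, k] = intercept + sum(
                c * df[name].to_numpy(dtype=float) for name, c in coefs.items()
            )
        p = np.exp(eta - eta.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        classes = np.array([rng.choice(K, p=row) for row in p])
    df["class_true"] = classes
    return df


def systematic_utility(profile: Profile, beta, schema,
                       coding: CodingScheme) -> float:
    """Linear systematic utility V = x' beta of one coded scenario."""
    if isinstance(beta, dict):
        beta = beta_from_dict(beta, schema, coding)
    x = code_profile(profile, schema, coding)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != x.shape:
        raise ValueError(
            f"beta has {beta.shape[0]} entries, coding expects {x.shape[0]}"
        )
    return float(x @ beta)


def choice_probability(choice_set: ChoiceSet, beta, schema,
                       coding: CodingScheme,
                       position_constant: float = 0.0) -> float:
    """Logit probability of choosing alternative A.

    ``P(A) = logistic(V_A - V_B + c)`` with ``c`` an optional constant
    for the A position (default 0: unlabeled alternatives).
    """
    va = systematic_utility(choice_set.a, beta, schema, coding)
    vb = systematic_utility(choice_set.b, beta, schema, coding)
    return float(expit(va - vb + position_constant))


def _records_for(respondent_id, plan, answered_sets, choices):
    rows = []
    for cs in answered_sets:
        choice = choices[cs.id]
        for alt_label, prof in (("A", cs.a), ("B", cs.b)):
            row = {"respondent_id": respondent_id, "choice_set_id": cs.id,
                   "alternative": alt_label,
                   "chosen": 1 if alt_label == choice else 0}
            row.update(prof.values(plan.schema))
            rows.append(row)
    return rows


def simulate_dataset(plan: DesignPlan, respondents: pd.DataFrame,
                     pop_model: PopulationModel,
                     config: SimulationConfig | None = None,
                     seed: int | None = None,
                     coding: CodingScheme | None = None) -> ChoiceDataset:
    """Simulate one questionnaire round over a drawn respondent table.

    Each responding, complete, non-careless respondent answers every
    choice set with A chosen with probability
    :func:`choice_probability` under her latent class's coefficients;
    careless respondents answer uniformly at random.  Nonresponders and
    incomplete questionnaires are flagged in the respondent table, not
    dropped.  Deterministic given the seed; the generating truth is
    attached to ``meta``.
    """
    if config is None:
        config = SimulationConfig()
    if seed is None:
        seed = config.seed
    if coding is None:
        coding = default_coding(plan.schema)
    if "class_true" not in respondents.columns:
        raise ConfigError("respondent table lacks class_true; use draw_respondents")
    if respondents["class_true"].max() >= pop_model.n_classes:
        raise ConfigError("respondent classes exceed population classes")
    rng = np.random.default_rng(seed)
    n = len(respondents)

    # probability of choosing A for each set under each class
    p_a = {
        cs.id: [choice_probability(cs, b, plan.schema, coding)
                for b in pop_model.class_betas]
        for cs in plan.choice_sets
    }

    if config.exact_counts:
        n_nonresp = int(round(n * (1.0 - config.response_rate)))
        n_returned = n - n_nonresp
        n_incomplete = int(round(n_returned * config.incomplete_rate))
        order = rng.permutation(n)
        nonresp_ix = set(order[:n_nonresp].tolist())
        incomplete_ix = set(order[n_nonresp:n_nonresp + n_incomplete].tolist())
    else:
        u = rng.random(n)
        nonresp_ix = set(np.flatnonzero(u >= config.response_rate).tolist())
        v = rng.random(n)
        incomplete_ix = set(np.flatnonzero(v < config.incomplete_rate).tolist()) \
            - nonresp_ix
    careless = rng.random(n) < config.careless_rate

    all_rows = []
    returned_flags, complete_flags = [], []
    n_sets = len(plan.choice_sets)
    for i, resp in enumerate(respondents.itertuples(index=False)):
        rid = resp.respondent_id
        k = int(resp.class_true)
        if i in nonresp_ix:
            returned_flags.append(0)
            complete_flags.append(0)
            continue
        returned_flags.append(1)
        if i in incomplete_ix:
            complete_flags.append(0)
            n_answered = int(rng.integers(0, n_sets))  # leaves >=1 unanswered
            answered = [plan.choice_sets[j]
                        for j in sorted(rng.choice(n_sets, size=n_answered,
                                                   replace=False))]
        else:
            complete_flags.append(1)
            answered = list(plan.choice_sets)
        choices = {}
        for cs in answered:
            if careless[i]:
                p = 0.5
            elif cs.is_dominance_test and config.exact_counts:
                # deterministic fixture: attentive respondents always pass
                choices[cs.id] = is_dominant(cs, plan.schema)
                continue
            else:
                p = p_a[cs.id][k]
            choices[cs.id] = "A" if rng.random() < p else "B"
        all_rows.extend(_records_for(rid, plan, answered, choices))

    resp_out = respondents.copy()
    resp_out["returned"] = returned_flags
    resp_out["complete"] = complete_flags
    resp_out["careless"] = careless.astype(int)

    records = pd.DataFrame(all_rows) if all_rows else pd.DataFrame(
        columns=["respondent_id", "choice_set_id", "alternative", "chosen"]
        + [a.name for a in plan.schema]
    )

    if config.forced_dominance_failures > 0 and len(plan.dominance_sets):
        dom = plan.dominance_sets[0]
        loser = "B" if is_dominant(dom, plan.schema) == "A" else "A"
        eligible = [
            r for r, ret, comp, care in zip(
                resp_out["respondent_id"], returned_flags, complete_flags,
                careless)
            if ret and comp and not care
        ]
        if len(eligible) < config.forced_dominance_failures:
            raise ConfigError("not enough eligible respondents to force "
                              "dominance failures")
        forced = rng.choice(eligible, size=config.forced_dominance_failures,
                            replace=False)
        for rid in forced:
            mask = ((records["respondent_id"] == rid)
                    & (records["choice_set_id"] == dom.id))
            records.loc[mask, "chosen"] = (
                records.loc[mask, "alternative"] == loser
            ).astype(int)

    meta = {
        "seed": int(seed),
        "config": asdict(config),
        "truth": pop_model.to_dict(),
        "plan_seed": int(plan.seed),
    }
    return ChoiceDataset(records, resp_out, meta)


def simulate_study(n: int | None = None,
                   plan: DesignPlan | None = None,
                   pop_model: PopulationModel | None = None,
                   config: SimulationConfig | None = None,
                   seed: int = 0) -> tuple:
    """Convenience wrapper: draw respondents and simulate one round.

    Returns ``(dataset, plan)``.  Defaults: the fixture instrument, the
    two-class reference population and the study-conditions config.
    """
    if plan is None:
        plan = build_design(default_schema(), seed=0)
    if pop_model is None:
        pop_model = reference_population()
    if config is None:
        config = SimulationConfig(seed=seed)
    if n is None:
        n = config.n_invited
    respondents = draw_respondents(n, pop_model, seed=seed)
    dataset = simulate_dataset(plan, respondents, pop_model, config,
                               seed=seed + 1)
    return dataset, plan
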