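"""Construction and validation of a two-alternative discrete choice instrument.

A discrete choice experiment (DCE) presents respondents with pairs of
hypothetical treatment scenarios, each described by the same set of
attributes at varying levels.  This module builds such an instrument:

* enumerate the full factorial of an attribute/level schema,
* select a balanced, near-orthogonal fraction of scenarios,
* randomly pair scenarios into binary choice sets, and
* construct dominance ("rationality") test sets in which one alternative
  is at least as good on every attribute, used to screen inattentive
  respondents.

The default schema describes an IVF/IVM treatment-choice instrument for
women at increased risk of ovarian hyperstimulation syndrome (OHSS):
chance of OHSS (safety), number of daily injections and chance of cycle
cancellation (burden), number of treatments needed to reach a 30% chance
of pregnancy (benefit), and out-of-pocket cost.  All five attributes are
oriented so that lower levels are preferable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AttributeSpec",
    "Profile",
    "ChoiceSet",
    "DesignPlan",
    "DesignError",
    "SchemaError",
    "IdentifiabilityError",
    "PairingError",
    "default_schema",
    "enumerate_full_factorial",
    "orthogonality_score",
    "select_fraction",
    "pair_profiles",
    "make_dominance_sets",
    "is_dominant",
    "required_sample_size",
    "build_design",
    "plan_to_json",
    "plan_from_json",
    "render_questionnaire",
]


class DesignError(ValueError):
    """Invalid design construction request."""


class SchemaError(DesignError):
    """Attribute/level schema is malformed."""


class IdentifiabilityError(DesignError):
    """Requested fraction is too small to identify a main-effects model."""


class PairingError(DesignError):
    """Scenario pool cannot be paired into valid choice sets."""


@dataclass(frozen=True)
class AttributeSpec:
    """One attribute of the instrument and its admissible levels.

    Parameters
    ----------
    name
        Short identifier, used as a column name in long-format data.
    levels
        Strictly increasing numeric level values (at least two).
    preference_direction
        ``-1`` if lower values are desirable (the default; true of all
        five attributes in the OHSS instrument), ``+1`` if higher.
    coding_default
        Preferred coding for estimation, ``"continuous"`` or
        ``"categorical"``; may be overridden per fit.
    continuous_scale
        Units per coefficient under continuous coding, e.g. ``1000`` for
        a cost attribute whose coefficient is per €1000.
    level_format
        Format string used when rendering the questionnaire.
    """

    name: str
    levels: tuple
    preference_direction: int = -1
    coding_default: str = "continuous"
    continuous_scale: float = 1.0
    level_format: str = "{}"

    def __post_init__(self):
        if len(self.levels) < 2:
            raise SchemaError(f"attribute {self.name!r} needs >=2 levels")
        lv = list(self.levels)
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise SchemaError(
                f"attribute {self.name!r}: levels must be strictly increasing"
            )
        if self.preference_direction not in (-1, 1):
            raise SchemaError("preference_direction must be -1 or +1")
        if self.coding_default not in ("continuous", "categorical"):
            raise SchemaError("coding_default must be continuous or categorical")
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def format_level(self, value) -> str:
        return self.level_format.format(value)


@dataclass(frozen=True)
class Profile:
    """A single treatment scenario: one 0-based level index per attribute."""

    level_indices: tuple

    def __post_init__(self):
        object.__setattr__(self, "level_indices", tuple(int(i) for i in self.level_indices))

    def values(self, schema) -> dict:
        """Raw level values keyed by attribute name."""
        _check_profile(self, schema)
        return {a.name: a.levels[i] for a, i in zip(schema, self.level_indices)}


@dataclass(frozen=True)
class ChoiceSet:
    """A binary question: two scenarios A and B, possibly a dominance test."""

    id: str
    a: Profile
    b: Profile
    is_dominance_test: bool = False

    @property
    def alternatives(self):
        return (self.a, self.b)


@dataclass(frozen=True)
class DesignPlan:
    """A complete instrument: schema, scenario pool and choice sets.

    ``scenario_pool`` holds the 2k scenarios of the orthogonal fraction,
    each of which appears in exactly one of the k estimation sets.
    Dominance-test sets are flagged; by default their scenarios are
    constructed separately and are not members of the pool.
    """

    schema: tuple
    scenario_pool: tuple
    choice_sets: tuple
    seed: int = 0

    @property
    def estimation_sets(self):
        return tuple(cs for cs in self.choice_sets if not cs.is_dominance_test)

    @property
    def dominance_sets(self):
        return tuple(cs for cs in self.choice_sets if cs.is_dominance_test)

    @property
    def set_ids(self):
        return tuple(cs.id for cs in self.choice_sets)

    def attribute(self, name: str) -> AttributeSpec:
        for a in self.schema:
            if a.name == name:
                return a
        raise KeyError(f"no attribute named {name!r}")

    def validate(self) -> None:
        """Check structural invariants; raise :class:`DesignError` on failure."""
        counts: dict = {}
        for cs in self.estimation_sets:
            for p in cs.alternatives:
                counts[p.level_indices] = counts.get(p.level_indices, 0) + 1
        for p in self.scenario_pool:
            if counts.get(p.level_indices, 0) != 1:
                raise DesignError(
                    f"pooled scenario {p.level_indices} must appear in exactly "
                    "one estimation set"
                )
        for cs in self.dominance_sets:
            if is_dominant(cs, self.schema) is None:
                raise DesignError(f"dominance set {cs.id} has no dominant winner")


def _check_profile(profile: Profile, schema) -> None:
    if len(profile.level_indices) != len(schema):
        raise SchemaError("profile has wrong number of attributes")
    for a, i in zip(schema, profile.level_indices):
        if not 0 <= i < a.n_levels:
            raise SchemaError(f"level index {i} out of range for {a.name!r}")


def default_schema() -> tuple:
    """The five-attribute OHSS-risk IVF/IVM instrument schema.

    Levels are listed best-to-worst (all attributes: lower is desirable).
    Pregnancy benefit is expressed as the number of treatments needed to
    reach a 30% chance of pregnancy; cost coefficients are per €1000 when
    coded continuously; injections default to categorical coding because
    their effect on preference is non-linear.
    """
    return (
        AttributeSpec("ohss", (0, 5, 10), level_format="{}%"),
        AttributeSpec("injections", (0, 4, 20), coding_default="categorical"),
        AttributeSpec("pregnancy", (1, 2, 3, 4),
                      level_format="30% after {} treatment(s)"),
        AttributeSpec("cancellation", (0, 5, 10, 15), level_format="{}%"),
        AttributeSpec("cost", (0, 1000, 2000, 3000), continuous_scale=1000.0,
                      level_format="€{}"),
    )


def enumerate_full_factorial(schema) -> list:
    """All level combinations of the schema, in lexicographic order."""
    if len(schema) == 0:
        raise SchemaError("schema is empty")
    return [
        Profile(ix)
        for ix in itertools.product(*(range(a.n_levels) for a in schema))
    ]


def _level_matrix(profiles, schema) -> np.ndarray:
    m = np.array([p.level_indices for p in profiles], dtype=np.intp)
    if m.shape[1] != len(schema):
        raise SchemaError("profiles do not match schema")
    return m


def orthogonality_score(profiles, schema) -> float:
    """Deviation of a scenario subset from a balanced orthogonal array.

    The penalty sums, over attributes, the normalised absolute deviation
    of level counts from perfect balance, and, over attribute pairs, the
    deviation of joint level-combination counts from independence.  It is
    zero exactly when the subset is a balanced orthogonal array for the
    schema (e.g. the full factorial) and grows with imbalance and with
    level-pair confounding.
    """
    if len(profiles) == 0:
        raise DesignError("empty profile subset")
    m = _level_matrix(profiles, schema)
    n = m.shape[0]
    score = 0.0
    for j, a in enumerate(schema):
        counts = np.bincount(m[:, j], minlength=a.n_levels)
        score += float(np.abs(counts - n / a.n_levels).sum()) / n
    for j, k in itertools.combinations(range(len(schema)), 2):
        lj, lk = schema[j].n_levels, schema[k].n_levels
        joint = np.bincount(m[:, j] * lk + m[:, k], minlength=lj * lk)
        score += float(np.abs(joint - n / (lj * lk)).sum()) / n
    return score


def _n_main_effect_params(schema) -> int:
    # main-effects categorical parameterisation (no intercept: a paired
    # difference design identifies attribute effects only)
    return sum(a.n_levels - 1 for a in schema)


def select_fraction(profiles, schema, size: int, seed: int = 0,
                    n_iter: int = 2000) -> list:
    """Select a near-orthogonal fractional design by greedy swap search.

    Starting from a seeded random ``size``-subset of ``profiles``, single
    member/non-member swaps are proposed and accepted only when they
    strictly decrease :func:`orthogonality_score`; the result is
    deterministic given ``seed`` and never scores worse than the initial
    random subset.
    """
    if size > len(profiles):
        raise DesignError("size exceeds pool size")
    if size < _n_main_effect_params(schema):
        raise IdentifiabilityError(
            f"size {size} cannot identify the main-effects model "
            f"({_n_main_effect_params(schema)} parameters)"
        )
    if size == len(profiles):
        return list(profiles)
    rng = np.random.default_rng(seed)
    pool = np.arange(len(profiles))
    chosen = rng.choice(pool, size=size, replace=False)
    out = ~np.isin(pool, chosen)
    outside = pool[out]
    current = [profiles[i] for i in chosen]
    score = orthogonality_score(current, schema)
    for _ in range(n_iter):
        i = rng.integers(size)
        j = rng.integers(len(outside))
        cand = list(current)
        cand[i] = profiles[outside[j]]
        cand_score = orthogonality_score(cand, schema)
        if cand_score < score:
            swapped_out = chosen[i]
            chosen[i], outside[j] = outside[j], swapped_out
            current = cand
            score = cand_score
    return current


def pair_profiles(profiles, seed: int = 0, id_prefix: str = "set",
                  max_attempts: int = 200) -> list:
    """Randomly pair an even pool of scenarios into binary choice sets.

    A pairing in which any set's two alternatives are identical in all
    attributes is redrawn (a choice between identical treatments carries
    no preference information).  Deterministic given ``seed``.
    """
    n = len(profiles)
    if n % 2 != 0:
        raise PairingError(f"cannot pair an odd number of profiles ({n})")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        pairs = [(profiles[perm[2 * i]], profiles[perm[2 * i + 1]])
                 for i in range(n // 2)]
        if all(a.level_indices != b.level_indices for a, b in pairs):
            return [
                ChoiceSet(f"{id_prefix}-{i + 1}", a, b)
                for i, (a, b) in enumerate(pairs)
            ]
    raise PairingError(
        "could not find a pairing without identical-alternative sets"
    )


def is_dominant(choice_set: ChoiceSet, schema):
    """Return ``"A"`` or ``"B"`` if that alternative weakly dominates the
    other on every attribute and strictly on at least one, else ``None``.
    """
    a, b = choice_set.a, choice_set.b
    _check_profile(a, schema)
    _check_profile(b, schema)

    def dominates(x, y):
        strict = False
        for attr, xi, yi in zip(schema, x.level_indices, y.level_indices):
            if attr.preference_direction == -1:
                if xi > yi:
                    return False
                strict = strict or xi < yi
            else:
                if xi < yi:
                    return False
                strict = strict or xi > yi
        return strict

    if dominates(a, b):
        return "A"
    if dominates(b, a):
        return "B"
    return None


def make_dominance_sets(schema, count: int, seed: int = 0,
                        id_prefix: str = "dom") -> list:
    """Construct ``count`` dominance (rationality) test sets.

    Alternative A carries the favourable level of every attribute; B
    draws each attribute uniformly from the unfavourable levels, so A
    strictly dominates on every attribute and an attentive respondent's
    answer is predictable.  Choosing B flags the respondent for
    exclusion.
    """
    if count < 0:
        raise DesignError("count must be >= 0")
    rng = np.random.default_rng(seed)
    a_ix = tuple(0 if a.preference_direction == -1 else a.n_levels - 1
                 for a in schema)
    sets = []
    for i in range(count):
        b_ix = []
        for attr in schema:
            if attr.preference_direction == -1:
                b_ix.append(int(rng.integers(1, attr.n_levels)))
            else:
                b_ix.append(int(rng.integers(0, attr.n_levels - 1)))
        sets.append(ChoiceSet(f"{id_prefix}-{i + 1}", Profile(a_ix),
                              Profile(tuple(b_ix)), is_dominance_test=True))
    return sets


def required_sample_size(schema, per_attribute: int = 20) -> int:
    """Rule-of-thumb target sample size: respondents per attribute times
    the number of attributes (default 20 per attribute)."""
    if per_attribute <= 0:
        raise DesignError("per_attribute must be positive")
    return per_attribute * len(schema)


def build_design(schema=None, n_sets: int = 16, n_dominance: int = 2,
                 seed: int = 0, dominance_from_pool: bool = False,
                 n_iter: int = 2000) -> DesignPlan:
    """Build the full instrument: fraction, pairing and dominance tests.

    With the defaults this reproduces the fixture instrument: a
    28-scenario near-orthogonal fraction paired into 14 estimation sets,
    plus 2 separately constructed dominance sets, i.e. 16 questions over
    32 scenarios.  With ``dominance_from_pool=True`` the fraction has
    ``2 * n_sets`` scenarios and the dominance pairs are searched for
    within it instead of being appended.
    """
    if schema is None:
        schema = default_schema()
    schema = tuple(schema)
    if n_dominance > n_sets:
        raise DesignError("more dominance sets than total sets")
    factorial = enumerate_full_factorial(schema)

    if not dominance_from_pool:
        n_est = n_sets - n_dominance
        pool = select_fraction(factorial, schema, 2 * n_est, seed=seed,
                               n_iter=n_iter)
        est = pair_profiles(pool, seed=seed + 1)
        dom = make_dominance_sets(schema, n_dominance, seed=seed + 2)
        return DesignPlan(schema, tuple(pool), tuple(est) + tuple(dom),
                          seed=seed)

    pool = select_fraction(factorial, schema, 2 * n_sets, seed=seed,
                           n_iter=n_iter)
    rng = np.random.default_rng(seed + 3)
    order = rng.permutation(len(pool))
    used: set = set()
    dom = []
    for i in order:
        if len(dom) == n_dominance:
            break
        if i in used:
            continue
        for j in order:
            if j == i or j in used:
                continue
            cs = ChoiceSet(f"dom-{len(dom) + 1}", pool[i], pool[j],
                           is_dominance_test=True)
            if is_dominant(cs, schema) == "A":
                dom.append(cs)
                used.update((int(i), int(j)))
                break
    if len(dom) < n_dominance:
        raise DesignError(
            "pool does not contain enough dominant pairs; use "
            "dominance_from_pool=False"
        )
    rest = [p for k, p in enumerate(pool) if k not in used]
    est = pair_profiles(rest, seed=seed + 1)
    return DesignPlan(schema, tuple(pool), tuple(est) + tuple(dom), seed=seed)


# ---------------------------------------------------------------------------
# serialisation and rendering

def _schema_to_obj(schema):
    return [
        {
            "name": a.name,
            "levels": list(a.levels),
            "preference_direction": a.preference_direction,
            "coding_default": a.coding_default,
            "continuous_scale": a.continuous_scale,
            "level_format": a.level_format,
        }
        for a in schema
    ]


def _schema_from_obj(obj):
    return tuple(
        AttributeSpec(
            d["name"], tuple(d["levels"]), d.get("preference_direction", -1),
            d.get("coding_default", "continuous"),
            d.get("continuous_scale", 1.0), d.get("level_format", "{}"),
        )
        for d in obj
    )


def plan_to_json(plan: DesignPlan) -> str:
    obj = {
        "schema": _schema_to_obj(plan.schema),
        "seed": plan.seed,
        "scenario_pool": [list(p.level_indices) for p in plan.scenario_pool],
        "choice_sets": [
            {
                "id": cs.id,
                "a": list(cs.a.level_indices),
                "b": list(cs.b.level_indices),
                "is_dominance_test": cs.is_dominance_test,
            }
            for cs in plan.choice_sets
        ],
    }
    return json.dumps(obj, indent=2)


def plan_from_json(text: str) -> DesignPlan:
    obj = json.loads(text)
    schema = _schema_from_obj(obj["schema"])
    pool = tuple(Profile(tuple(ix)) for ix in obj["scenario_pool"])
    sets = tuple(
        ChoiceSet(d["id"], Profile(tuple(d["a"])), Profile(tuple(d["b"])),
                  d["is_dominance_test"])
        for d in obj["choice_sets"]
    )
    return DesignPlan(schema, pool, sets, seed=obj.get("seed", 0))


def render_questionnaire(plan: DesignPlan) -> str:
    """Plain-text questionnaire: each choice set as a two-column table."""
    lines = []
    width = max(len(a.name) for a in plan.schema) + 2
    for q, cs in enumerate(plan.choice_sets, start=1):
        lines.append(f"Question {q}: which treatment do you prefer?")
        va, vb = cs.a.values(plan.schema), cs.b.values(plan.schema)
        lines.append(f"  {'':{width}}  {'Treatment A':<28}Treatment B")
        for a in plan.schema:
            fa = a.format_level(va[a.name])
            fb = a.format_level(vb[a.name])
            lines.append(f"  {a.name:{width}}  {fa:<28}{fb}")
        lines.append("")
    return "\n".join(lines)
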