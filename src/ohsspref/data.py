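"""Long-format choice data: I/O, validation, exclusions and summaries.

The canonical container is :class:`ChoiceDataset`: one record per
respondent x choice set x alternative, carrying the raw attribute level
values of that alternative and a ``chosen`` flag, plus a respondent
table with covariates.  Datasets round-trip losslessly through a
delimited text file with a JSON sidecar (seeds, ground truth, and the
respondent table, which must also cover invited women who returned
nothing and therefore have no long-format rows).

:func:`apply_exclusions` reproduces the screening cascade of a postal
DCE study: invited -> returned -> complete -> passed the dominance
(rationality) tests, with an audit log, and drops the dominance sets
themselves from the estimation records.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignPlan, is_dominant

__all__ = [
    "ChoiceDataset",
    "ExclusionLog",
    "ValidationError",
    "read_choice_data",
    "write_choice_data",
    "validate_dataset",
    "apply_exclusions",
    "filter_respondents",
    "summarize_sample",
]

#: respondent-table columns that are bookkeeping, not covariates
FLAG_COLUMNS = ("respondent_id", "returned", "complete", "careless",
                "class_true")


class ValidationError(ValueError):
    """Dataset violates the documented long-format dialect."""


@dataclass
class ChoiceDataset:
    """Long-format stated-choice records plus a respondent table.

    ``records`` columns: ``respondent_id``, ``choice_set_id``,
    ``alternative`` ("A"/"B"), one column per attribute (raw level
    value), ``chosen`` (0/1).  Unanswered sets have no rows.
    ``respondents`` has one row per invited respondent (covariates and
    simulation flags); ``meta`` holds seeds and, for simulated data,
    the generating ground truth.
    """

    records: pd.DataFrame
    respondents: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def respondent_ids(self):
        return list(self.respondents["respondent_id"])

    @property
    def n_respondents(self) -> int:
        return len(self.respondents)

    def covariate_columns(self):
        return [c for c in self.respondents.columns if c not in FLAG_COLUMNS]

    def copy(self) -> "ChoiceDataset":
        return ChoiceDataset(self.records.copy(), self.respondents.copy(),
                             json.loads(json.dumps(self.meta)))


def write_choice_data(dataset: ChoiceDataset, path) -> None:
    """Write records as CSV and respondents/meta as a ``.meta.json`` sidecar."""
    dataset.records.to_csv(path, index=False)
    sidecar = {
        "respondents": dataset.respondents.to_dict(orient="list"),
        "meta": dataset.meta,
    }
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")


def read_choice_data(path, plan: DesignPlan | None = None) -> ChoiceDataset:
    """Read a dataset written by :func:`write_choice_data`.

    If the sidecar is absent the respondent table is reconstructed from
    the record ids (covariates lost).  When ``plan`` is given the
    dataset is validated against it.
    """
    records = pd.read_csv(path)
    sidecar_path = f"{path}.meta.json"
    if os.path.exists(sidecar_path):
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        respondents = pd.DataFrame(sidecar["respondents"])
        meta = sidecar.get("meta", {})
    else:
        respondents = pd.DataFrame(
            {"respondent_id": sorted(records["respondent_id"].unique())}
        )
        meta = {}
    ds = ChoiceDataset(records, respondents, meta)
    if plan is not None:
        validate_dataset(ds, plan)
    return ds


def validate_dataset(dataset: ChoiceDataset, plan: DesignPlan) -> None:
    """Check the dataset against the design plan; raise on the first
    offending record, naming it."""
    rec = dataset.records
    required = {"respondent_id", "choice_set_id", "alternative", "chosen"}
    missing = required - set(rec.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    known_sets = set(plan.set_ids)
    set_lookup = {cs.id: cs for cs in plan.choice_sets}
    levels = {a.name: set(a.levels) for a in plan.schema}
    for name, allowed in levels.items():
        if name not in rec.columns:
            raise ValidationError(f"missing attribute column {name!r}")
        bad = rec.loc[~rec[name].isin(allowed)]
        if len(bad):
            r = bad.iloc[0]
            raise ValidationError(
                f"respondent {r['respondent_id']} set {r['choice_set_id']}: "
                f"unknown level {r[name]!r} for attribute {name!r}"
            )
    unknown = rec.loc[~rec["choice_set_id"].isin(known_sets)]
    if len(unknown):
        r = unknown.iloc[0]
        raise ValidationError(
            f"respondent {r['respondent_id']}: choice set "
            f"{r['choice_set_id']!r} not in the design plan"
        )
    for (rid, sid), grp in rec.groupby(["respondent_id", "choice_set_id"],
                                       sort=False):
        alts = sorted(grp["alternative"])
        if alts != ["A", "B"]:
            raise ValidationError(
                f"respondent {rid} set {sid}: expected alternatives A and B, "
                f"got {alts}"
            )
        n_chosen = int(grp["chosen"].sum())
        if n_chosen != 1:
            raise ValidationError(
                f"respondent {rid} set {sid}: {n_chosen} alternatives chosen "
                "(exactly one required)"
            )
        cs = set_lookup[sid]
        for alt_label, prof in (("A", cs.a), ("B", cs.b)):
            row = grp.loc[grp["alternative"] == alt_label].iloc[0]
            expect = prof.values(plan.schema)
            for name, val in expect.items():
                if row[name] != val:
                    raise ValidationError(
                        f"respondent {rid} set {sid} alternative {alt_label}: "
                        f"{name}={row[name]!r} does not match the plan "
                        f"({val!r})"
                    )


@dataclass
class ExclusionLog:
    """Audit trail of the screening cascade.

    ``stages`` maps stage name -> surviving respondent ids, in order
    invited, returned, complete, rational; ``reasons`` maps each
    excluded id to why it left the cascade.
    """

    stages: dict
    reasons: dict

    @property
    def counts(self) -> dict:
        return {k: len(v) for k, v in self.stages.items()}

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "stages": {k: list(v) for k, v in self.stages.items()},
            "reasons": dict(self.reasons),
        }


def apply_exclusions(dataset: ChoiceDataset, plan: DesignPlan):
    """Apply the screening cascade and drop dominance sets.

    Respondents are excluded if they returned nothing, answered fewer
    than all choice sets, or chose the dominated alternative on at
    least one dominance test.  Dominance-set records never enter the
    returned analysis dataset: they screen respondents but do not
    contribute to the likelihood.  Returns ``(analysis_dataset, log)``.
    """
    rec = dataset.records
    invited = list(dataset.respondents["respondent_id"])
    answered = (
        rec.loc[rec["chosen"] == 1]
        .groupby("respondent_id")["choice_set_id"].nunique()
        if len(rec) else pd.Series(dtype=int)
    )
    returned = [r for r in invited if answered.get(r, 0) > 0]
    n_sets = len(plan.choice_sets)
    complete = [r for r in returned if answered.get(r, 0) == n_sets]

    dom_ids = [cs.id for cs in plan.dominance_sets]
    winners = {cs.id: is_dominant(cs, plan.schema)
               for cs in plan.dominance_sets}
    chosen = rec.loc[(rec["chosen"] == 1) & rec["choice_set_id"].isin(dom_ids),
                     ["respondent_id", "choice_set_id", "alternative"]]
    failed = set()
    for _, row in chosen.iterrows():
        if row["alternative"] != winners[row["choice_set_id"]]:
            failed.add(row["respondent_id"])
    rational = [r for r in complete if r not in failed]

    reasons = {}
    for r in invited:
        if r not in returned:
            reasons[r] = "did not return the questionnaire"
        elif r not in complete:
            reasons[r] = "incomplete questionnaire"
        elif r not in rational:
            reasons[r] = "failed a dominance (rationality) test"
    log = ExclusionLog(
        stages={"invited": invited, "returned": returned,
                "complete": complete, "rational": rational},
        reasons=reasons,
    )
    keep = set(rational)
    est_ids = {cs.id for cs in plan.estimation_sets}
    out_rec = rec.loc[
        rec["respondent_id"].isin(keep) & rec["choice_set_id"].isin(est_ids)
    ].reset_index(drop=True)
    out_resp = dataset.respondents.loc[
        dataset.respondents["respondent_id"].isin(keep)
    ].reset_index(drop=True)
    return ChoiceDataset(out_rec, out_resp, dict(dataset.meta)), log


def filter_respondents(dataset: ChoiceDataset, predicate) -> ChoiceDataset:
    """Keep respondents for whom ``predicate(row)`` is truthy.

    ``predicate`` receives each respondent-table row as a Series; used
    e.g. for the sensitivity refit excluding women pregnant at the time
    of the questionnaire.
    """
    mask = dataset.respondents.apply(predicate, axis=1).astype(bool)
    keep = set(dataset.respondents.loc[mask, "respondent_id"])
    return ChoiceDataset(
        dataset.records.loc[
            dataset.records["respondent_id"].isin(keep)
        ].reset_index(drop=True),
        dataset.respondents.loc[mask].reset_index(drop=True),
        dict(dataset.meta),
    )


def summarize_sample(dataset: ChoiceDataset, columns=None) -> pd.DataFrame:
    """Descriptive summary of respondent covariates.

    Continuous covariates get mean and SD; binary and nominal ones get
    n and percent per level; an all-missing column is reported as
    missing rather than raising.
    """
    if dataset.n_respondents == 0:
        raise ValidationError("empty dataset")
    resp = dataset.respondents
    if columns is None:
        columns = dataset.covariate_columns()
    rows = []
    n_total = len(resp)
    for col in columns:
        s = resp[col]
        if s.notna().sum() == 0:
            rows.append({"covariate": col, "kind": "missing"})
            continue
        vals = s.dropna()
        is_binary = set(pd.unique(vals)) <= {0, 1, True, False}
        if pd.api.types.is_numeric_dtype(vals) and not is_binary:
            rows.append({
                "covariate": col, "kind": "continuous",
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            })
        elif is_binary:
            n = int(vals.astype(bool).sum())
            rows.append({
                "covariate": col, "kind": "binary", "n": n,
                "percent": 100.0 * n / n_total,
            })
        else:
            for level, n in vals.value_counts().items():
                rows.append({
                    "covariate": f"{col}={level}", "kind": "nominal",
                    "n": int(n), "percent": 100.0 * int(n) / n_total,
                })
    return pd.DataFrame(rows)
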