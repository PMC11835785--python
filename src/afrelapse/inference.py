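"""Exact conditional-probability queries under full, partial or no evidence.

The default schema's joint state space (20,736 cells) is small enough to
enumerate, so queries are answered exactly: the full joint tensor is built
once per fitted network, evidence axes are fixed by indexing, the
remaining non-target axes are summed out, and the result is normalized.
Variables absent from the evidence are thereby marginalized — this is the
mechanism by which the model still predicts relapse when, say, left-atrial
volume and epicardial fat were never measured for a patient.

Evidence whose probability is exactly zero under the network raises
:class:`ImpossibleEvidenceError` rather than returning NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import Cohort
from .exceptions import ImpossibleEvidenceError, InvalidParameterError, SchemaMismatchError
from .network import FittedNetwork

__all__ = ["Evidence", "QueryResult", "joint_probability", "query", "predict_cohort"]

# joint tensors cached per fitted network (keyed by id; networks are frozen)
_joint_cache: dict[int, tuple[FittedNetwork, np.ndarray]] = {}


def _joint_tensor(network: FittedNetwork) -> np.ndarray:
    entry = _joint_cache.get(id(network))
    if entry is not None and entry[0] is network:
        return entry[1]
    tensor = network.joint_table()
    _joint_cache.clear()  # keep at most one; callers loop over many refits
    _joint_cache[id(network)] = (network, tensor)
    return tensor


@dataclass(frozen=True)
class Evidence:
    """A partial assignment of observed variables to states."""

    assignments: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass(frozen=True)
class QueryResult:
    """Posterior distribution of the target given the evidence used."""

    target: str
    states: tuple[str, ...]
    distribution: np.ndarray
    evidence_used: Evidence

    def __getitem__(self, state: str) -> float:
        return float(self.distribution[self.states.index(state)])


def joint_probability(network: FittedNetwork, assignment: Mapping[str, str]) -> float:
    """P(full assignment) as the product of CPT entries along the DAG."""
    schema = network.schema
    missing = set(schema.names) - set(assignment)
    if missing:
        raise InvalidParameterError(
            f"assignment must cover every node; missing {sorted(missing)}"
        )
    idx = tuple(
        schema[name].state_index(assignment[name]) for name in schema.names
    )
    return float(_joint_tensor(network)[idx])


def query(network: FittedNetwork, target: str, evidence: Evidence | Mapping[str, str]) -> QueryResult:
    """Exact P(target | evidence) by enumeration over the joint.

    Unobserved variables are summed out.  Empty evidence yields the
    marginal of the target.
    """
    if not isinstance(evidence, Evidence):
        evidence = Evidence(evidence)
    schema = network.schema
    if target not in schema:
        raise SchemaMismatchError(f"unknown target {target!r}")
    if target in evidence.assignments:
        raise InvalidParameterError(f"target {target!r} appears in evidence")

    indexer: list[object] = [slice(None)] * len(schema.variables)
    for name, state in evidence.assignments.items():
        indexer[schema.index(name)] = schema[name].state_index(state)
    sub = _joint_tensor(network)[tuple(indexer)]
    # axes of `sub` correspond to the unassigned variables in schema order
    free = [n for n in schema.names if n not in evidence.assignments]
    target_axis = free.index(target)
    dist = sub.sum(axis=tuple(i for i in range(sub.ndim) if i != target_axis))
    norm = float(dist.sum())
    if norm <= 0.0:
        raise ImpossibleEvidenceError(
            f"evidence {dict(evidence.assignments)} has probability 0"
        )
    return QueryResult(
        target=target,
        states=schema[target].states,
        distribution=dist / norm,
        evidence_used=evidence,
    )


def predict_cohort(
    network: FittedNetwork,
    cohort: Cohort,
    predictor_set: Sequence[str],
) -> np.ndarray:
    """Per-row P(outcome = positive | evidence on ``predictor_set``).

    Evidence for each row is its observed states restricted to the
    predictor set; all other variables are marginalized.  Row order is
    preserved.  The positive outcome state is the last state of the
    outcome variable ("true" in the default schema).
    """
    schema = network.schema
    outcome = schema.outcome_name
    predictor_set = list(predictor_set)
    for p in predictor_set:
        if p not in schema:
            raise SchemaMismatchError(f"unknown predictor {p!r}")
    if outcome in predictor_set:
        raise InvalidParameterError("predictor set must exclude the outcome")

    joint = _joint_tensor(network)
    keep = set(predictor_set) | {outcome}
    drop_axes = tuple(i for i, n in enumerate(schema.names) if n not in keep)
    marg = joint.sum(axis=drop_axes) if drop_axes else joint
    # axes of marg: predictors (schema order) then possibly outcome among them
    kept_names = [n for n in schema.names if n in keep]
    out_axis = kept_names.index(outcome)
    denom = marg.sum(axis=out_axis)
    pos = marg.take(indices=schema[outcome].cardinality - 1, axis=out_axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = pos / denom
    pred_names = [n for n in kept_names if n != outcome]
    cols = tuple(cohort.column(n) for n in pred_names)
    result = cond[cols] if cols else np.full(cohort.n, float(cond))
    if np.isnan(result).any():
        bad = int(np.flatnonzero(np.isnan(result))[0])
        raise ImpossibleEvidenceError(
            f"row {bad}: predictor configuration has probability 0 under the network"
        )
    return np.asarray(result, dtype=float)
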