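"""Score-based structure learning: BIC scoring and constrained hill climbing.

The network score is the decomposable BIC (higher is better): for node i
with r_i states and q_i parent configurations,

    local_i = max-loglik( x_i | parents_i )  -  (log n)/2 * (r_i - 1) * q_i,

summed over nodes.  Hill climbing starts from the whitelist-only graph and
greedily applies the single arc addition, deletion or reversal with the
largest score improvement, subject to the constraints (whitelist arcs are
inviolable, blacklist arcs are never added, acyclicity is preserved),
stopping when no move improves the score.  Move enumeration is in
lexicographic (operation, parent, child) order with the first maximal
improvement taken, so the procedure is deterministic without a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .cohort import Cohort
from .exceptions import InvalidConstraintsError, SchemaMismatchError
from .network import Arc, NetworkStructure, _as_arcset

__all__ = [
    "StructureScore",
    "ArcConstraints",
    "bic_score",
    "local_bic",
    "hill_climb",
    "default_constraints",
    "default_ground_truth_arcs",
    "structural_hamming_distance",
]


@dataclass(frozen=True)
class StructureScore:
    """Decomposed network score; ``total`` is the sum of ``per_node``."""

    total: float
    per_node: dict[str, float]
    n: int
    score_name: str = "bic"


@dataclass(frozen=True)
class ArcConstraints:
    """Whitelist (forced) and blacklist (forbidden) arc sets."""

    whitelist: frozenset[Arc] = frozenset()
    blacklist: frozenset[Arc] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "whitelist", _as_arcset(self.whitelist))
        object.__setattr__(self, "blacklist", _as_arcset(self.blacklist))
        if self.whitelist & self.blacklist:
            raise InvalidConstraintsError(
                f"arcs both whitelisted and blacklisted: "
                f"{sorted(self.whitelist & self.blacklist)}"
            )
        g = nx.DiGraph(list(self.whitelist))
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidConstraintsError("whitelist alone contains a cycle")

    @classmethod
    def from_json(cls, text: str) -> "ArcConstraints":
        d = json.loads(text)
        return cls(
            whitelist=_as_arcset(d.get("whitelist", [])),
            blacklist=_as_arcset(d.get("blacklist", [])),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "whitelist": sorted([list(a) for a in self.whitelist]),
                "blacklist": sorted([list(a) for a in self.blacklist]),
            },
            indent=2,
        )


def local_bic(cohort: Cohort, child: str, parents: Sequence[str]) -> float:
    """BIC local score of one node given a candidate parent set."""
    schema = cohort.schema
    n = cohort.n
    r = schema[child].cardinality
    parent_cards = tuple(schema[p].cardinality for p in parents)
    q = int(np.prod(parent_cards)) if parent_cards else 1
    shape = parent_cards + (r,)
    cols = [cohort.column(p) for p in parents] + [cohort.column(child)]
    flat = np.ravel_multi_index(cols, shape)
    counts = np.bincount(flat, minlength=int(np.prod(shape))).reshape(-1, r)
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(counts / row_tot), 0.0)
    return float(ll.sum()) - 0.5 * np.log(n) * (r - 1) * q


def bic_score(structure: NetworkStructure, cohort: Cohort) -> StructureScore:
    """Decomposable BIC of a structure on a complete cohort."""
    if set(structure.nodes) != set(cohort.schema.names):
        raise SchemaMismatchError("structure nodes differ from cohort schema")
    per_node = {
        node: local_bic(cohort, node, structure.parents(node))
        for node in structure.nodes
    }
    return StructureScore(total=sum(per_node.values()), per_node=per_node, n=cohort.n)


class _ScoreCache:
    """Memoizes local BIC scores by (child, parent set)."""

    def __init__(self, cohort: Cohort):
        self.cohort = cohort
        self._cache: dict[tuple[str, frozenset[str]], float] = {}

    def __call__(self, child: str, parents: Iterable[str]) -> float:
        parents = frozenset(parents)
        key = (child, parents)
        if key not in self._cache:
            ordered = tuple(p for p in self.cohort.schema.names if p in parents)
            self._cache[key] = local_bic(self.cohort, child, ordered)
        return self._cache[key]


def hill_climb(
    cohort: Cohort,
    constraints: ArcConstraints | None = None,
    max_parents: int | None = None,
    epsilon: float = 1e-9,
) -> NetworkStructure:
    """Greedy BIC hill climbing over DAGs under arc constraints.

    Returns a structure whose BIC is never below that of the whitelist-only
    starting graph.  ``max_parents`` optionally bounds in-degree (unbounded
    by default); ``epsilon`` is the minimum improvement treated as a gain.
    """
    constraints = constraints or ArcConstraints()
    nodes = tuple(cohort.schema.names)
    node_set = set(nodes)
    for p, c in constraints.whitelist | constraints.blacklist:
        if p not in node_set or c not in node_set:
            raise InvalidConstraintsError(f"constraint arc ({p!r}, {c!r}) uses unknown node")

    score = _ScoreCache(cohort)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(constraints.whitelist)

    def parents_of(c: str) -> frozenset[str]:
        return frozenset(g.predecessors(c))

    while True:
        best_gain = epsilon
        best_move: tuple[str, str, str] | None = None
        # candidate moves in lexicographic (operation, parent, child) order;
        # ties keep the first maximum
        for op in ("add", "delete", "reverse"):
            for p in nodes:
                for c in nodes:
                    if p == c:
                        continue
                    has = g.has_edge(p, c)
                    if op == "add":
                        if has or (p, c) in constraints.blacklist:
                            continue
                        if g.has_edge(c, p):
                            continue  # reversal is a separate move
                        if max_parents is not None and g.in_degree(c) >= max_parents:
                            continue
                        if nx.has_path(g, c, p):
                            continue  # would create a cycle
                        gain = score(c, parents_of(c) | {p}) - score(c, parents_of(c))
                    elif op == "delete":
                        if not has or (p, c) in constraints.whitelist:
                            continue
                        gain = score(c, parents_of(c) - {p}) - score(c, parents_of(c))
                    else:  # reverse (p, c) -> (c, p)
                        if not has or (p, c) in constraints.whitelist:
                            continue
                        if (c, p) in constraints.blacklist:
                            continue
                        if max_parents is not None and g.in_degree(p) >= max_parents:
                            continue
                        g.remove_edge(p, c)
                        creates_cycle = nx.has_path(g, p, c)
                        g.add_edge(p, c)
                        if creates_cycle:
                            continue
                        gain = (
                            score(c, parents_of(c) - {p})
                            - score(c, parents_of(c))
                            + score(p, parents_of(p) | {c})
                            - score(p, parents_of(p))
                        )
                    if gain > best_gain:
                        best_gain = gain
                        best_move = (op, p, c)
        if best_move is None:
            break
        op, p, c = best_move
        if op == "add":
            g.add_edge(p, c)
        elif op == "delete":
            g.remove_edge(p, c)
        else:
            g.remove_edge(p, c)
            g.add_edge(c, p)

    return NetworkStructure(
        nodes=nodes,
        arcs=frozenset(g.edges()),
        whitelist=constraints.whitelist,
        blacklist=constraints.blacklist,
    )


def _load_packaged_json(name: str) -> str:
    return resources.files("afrelapse.data").joinpath(name).read_text()


def default_constraints(path: str | Path | None = None) -> ArcConstraints:
    """Clinically motivated arc constraints for the 12-variable schema.

    The whitelist forces the seven established relapse predictors (age,
    sex, smoking, preablation AF type, left-atrial volume, epicardial fat,
    OSA) into the outcome node, plus risk-factor arcs into diabetes, high
    blood pressure and OSA.  The blacklist forbids every arc out of the
    outcome (the relapse node is a sink).  Shipped as an editable JSON
    file; pass ``path`` to load a customized copy.
    """
    text = (
        Path(path).read_text()
        if path is not None
        else _load_packaged_json("constraints_default.json")
    )
    return ArcConstraints.from_json(text)


def default_ground_truth_arcs() -> frozenset[Arc]:
    """Whitelisted arcs plus the data-driven arcs of the reference network.

    The data-driven set (bmi->epicardial_fat, osa->af_type,
    af_type->la_volume, sex->smoking, sex->alcoholism, sex->bmi) is the
    default generating structure for synthetic cohorts and the default
    fixed structure for validation runs.
    """
    d = json.loads(_load_packaged_json("constraints_default.json"))
    learned = json.loads(_load_packaged_json("learned_arcs_default.json"))
    return _as_arcset(d["whitelist"]) | _as_arcset(learned["arcs"])


def structural_hamming_distance(a: NetworkStructure, b: NetworkStructure) -> int:
    """Arc edits (insert/delete/reverse) transforming one DAG into another.

    Symmetric; zero iff the arc sets are identical.  A reversed arc counts
    as one edit.
    """
    if set(a.nodes) != set(b.nodes):
        raise SchemaMismatchError("structures are over different node sets")
    dist = 0
    seen: set[frozenset[str]] = set()
    for p, c in a.arcs | b.arcs:
        pair = frozenset((p, c))
        if pair in seen:
            continue
        seen.add(pair)
        a_has = ((p, c) in a.arcs, (c, p) in a.arcs)
        b_has = ((p, c) in b.arcs, (c, p) in b.arcs)
        if a_has != b_has:
            dist += 1
    return dist
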