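"""Network structure, conditional probability tables and Bayesian fitting.

A :class:`NetworkStructure` is a DAG over schema variables together with
the arc constraints it was learned under.  A :class:`FittedNetwork` adds
one CPT per node, estimated as the Dirichlet posterior mean under a
BDeu-style uniform prior: for child X with r states and q parent
configurations, every CPT cell receives the pseudo-count
``ESS / (r * q)``, where ESS is the equivalent sample size (the total
imaginary sample spread evenly over the table).  The posterior-mean cell
for state k under parent configuration j is then

    (N_xjk + ESS/(r q)) / (N_.j + ESS/q).

With ESS -> 0+ this reproduces maximum-likelihood frequencies wherever
counts are nonzero; with ESS >> n every table tends to uniform.  The
default ESS = 1 follows the common default of discrete Bayesian-network
toolkits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .cohort import Cohort
from .exceptions import (
    InvalidConstraintsError,
    InvalidParameterError,
    SchemaMismatchError,
)
from .schema import DomainSchema

__all__ = [
    "Arc",
    "NetworkStructure",
    "Cpt",
    "FittedNetwork",
    "fit_cpts",
    "loglikelihood",
]

Arc = tuple[str, str]


def _as_arcset(arcs: Iterable[Sequence[str]]) -> frozenset[Arc]:
    return frozenset((str(p), str(c)) for p, c in arcs)


@dataclass(frozen=True)
class NetworkStructure:
    """A DAG over named nodes with whitelist/blacklist constraints.

    Invariants enforced at construction: the arc set is acyclic, the
    whitelist is contained in the arcs, no arc is blacklisted, and the two
    constraint sets are disjoint.
    """

    nodes: tuple[str, ...]
    arcs: frozenset[Arc]
    whitelist: frozenset[Arc] = frozenset()
    blacklist: frozenset[Arc] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "arcs", _as_arcset(self.arcs))
        object.__setattr__(self, "whitelist", _as_arcset(self.whitelist))
        object.__setattr__(self, "blacklist", _as_arcset(self.blacklist))
        node_set = set(self.nodes)
        for p, c in self.arcs | self.whitelist | self.blacklist:
            if p not in node_set or c not in node_set:
                raise SchemaMismatchError(f"arc ({p!r}, {c!r}) uses unknown node")
        if self.whitelist & self.blacklist:
            raise InvalidConstraintsError("whitelist and blacklist overlap")
        if not self.whitelist <= self.arcs:
            raise InvalidConstraintsError("whitelist arcs missing from arc set")
        if self.arcs & self.blacklist:
            raise InvalidConstraintsError("arc set contains blacklisted arcs")
        if not nx.is_directed_acyclic_graph(self.to_digraph()):
            raise InvalidConstraintsError("arc set contains a directed cycle")

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents of a node in schema/node order (deterministic)."""
        return tuple(p for p in self.nodes if (p, node) in self.arcs)

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.to_digraph()))

    def with_arcs(self, arcs: Iterable[Arc]) -> "NetworkStructure":
        return NetworkStructure(self.nodes, frozenset(arcs), self.whitelist, self.blacklist)

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": list(self.nodes),
                "arcs": sorted([list(a) for a in self.arcs]),
                "whitelist": sorted([list(a) for a in self.whitelist]),
                "blacklist": sorted([list(a) for a in self.blacklist]),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkStructure":
        d = json.loads(text)
        return cls(
            nodes=tuple(d["nodes"]),
            arcs=_as_arcset(d["arcs"]),
            whitelist=_as_arcset(d.get("whitelist", [])),
            blacklist=_as_arcset(d.get("blacklist", [])),
        )

    def to_dot(self) -> str:
        """Graphviz DOT with whitelisted arcs grey and learned arcs orange."""
        lines = ["digraph afrelapse {", "  rankdir=LR;", "  node [shape=box];"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for p, c in sorted(self.arcs):
            color = "grey40" if (p, c) in self.whitelist else "orange"
            lines.append(f'  "{p}" -> "{c}" [color={color}];')
        lines.append("}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class Cpt:
    """P(child state | parent configuration) as a dense array.

    ``table`` has shape ``parent_cards + (child_card,)`` — one axis per
    parent in ``parents`` order, last axis over child states.  Every slice
    along the last axis sums to one.
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray = field(repr=False)
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=float)
        object.__setattr__(self, "table", table)
        object.__setattr__(self, "parents", tuple(self.parents))
        if self.pseudocount < 0:
            raise InvalidParameterError("pseudocount must be nonnegative")
        if table.ndim != len(self.parents) + 1:
            raise InvalidParameterError(
                f"CPT of {self.child!r}: table rank {table.ndim} != "
                f"{len(self.parents)} parents + 1"
            )
        if (table < 0).any() or (table > 1 + 1e-12).any():
            raise InvalidParameterError(f"CPT of {self.child!r}: entries outside [0,1]")
        sums = table.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise InvalidParameterError(
                f"CPT of {self.child!r}: rows do not normalize (max dev "
                f"{np.abs(sums - 1).max():.2e})"
            )
        if self.pseudocount > 0 and (table <= 0).any():
            raise InvalidParameterError(
                f"CPT of {self.child!r}: zero entry despite positive pseudocount"
            )

    @property
    def child_cardinality(self) -> int:
        return self.table.shape[-1]


@dataclass(frozen=True)
class FittedNetwork:
    """Structure plus one CPT per node, closed under the factorization

    P(x_1..x_m) = prod_i P(x_i | parents(x_i)).
    """

    schema: DomainSchema
    structure: NetworkStructure
    cpts: Mapping[str, Cpt]
    equivalent_sample_size: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cpts", dict(self.cpts))
        if set(self.cpts) != set(self.structure.nodes):
            raise SchemaMismatchError("CPT node set differs from structure nodes")
        for node, cpt in self.cpts.items():
            if cpt.parents != self.structure.parents(node):
                raise SchemaMismatchError(
                    f"CPT parents of {node!r} ({cpt.parents}) disagree with "
                    f"structure ({self.structure.parents(node)})"
                )

    def joint_table(self) -> np.ndarray:
        """The full joint as a dense tensor, one axis per schema variable.

        Feasible by design: the default schema has 2**8 * 3**4 = 20736
        cells.  Each CPT is broadcast along the axes of its child and
        parents and the factors multiplied.
        """
        shape = self.schema.cardinalities
        joint = np.ones(shape)
        m = len(shape)
        for node, cpt in self.cpts.items():
            axes = [self.schema.index(p) for p in cpt.parents] + [
                self.schema.index(node)
            ]
            # move the CPT's axes into joint axis positions, size-1 elsewhere
            expand = [1] * m
            for ax, size in zip(axes, cpt.table.shape):
                expand[ax] = size
            perm = np.argsort(axes)
            joint = joint * cpt.table.transpose(perm).reshape(expand)
        return joint


def _parent_config_count(structure: NetworkStructure, schema: DomainSchema, node: str) -> int:
    q = 1
    for p in structure.parents(node):
        q *= schema[p].cardinality
    return q


def fit_cpts(
    structure: NetworkStructure,
    cohort: Cohort | None,
    equivalent_sample_size: float = 1.0,
    schema: DomainSchema | None = None,
) -> FittedNetwork:
    """Bayesian CPT estimation with a uniform (BDeu-style) prior.

    Parameters
    ----------
    structure
        Fixed DAG whose nodes match the cohort schema variables.
    cohort
        Complete training records.  May be None (prior-only fit, every CPT
        uniform) when ``equivalent_sample_size > 0`` and ``schema`` given.
    equivalent_sample_size
        Total imaginary sample size of the Dirichlet prior; must be > 0
        for a proper posterior.  Spread evenly over each CPT's cells.
    """
    if equivalent_sample_size <= 0:
        raise InvalidParameterError("equivalent_sample_size must be positive")
    if cohort is None:
        if schema is None:
            raise InvalidParameterError("prior-only fit needs an explicit schema")
    else:
        schema = cohort.schema
    if set(structure.nodes) != set(schema.names):
        raise SchemaMismatchError("structure nodes differ from schema variables")

    cpts: dict[str, Cpt] = {}
    for node in schema.names:
        parents = structure.parents(node)
        r = schema[node].cardinality
        parent_cards = tuple(schema[p].cardinality for p in parents)
        q = int(np.prod(parent_cards)) if parent_cards else 1
        alpha = equivalent_sample_size / (r * q)
        shape = parent_cards + (r,)
        counts = np.zeros(shape)
        if cohort is not None:
            cols = [cohort.column(p) for p in parents] + [cohort.column(node)]
            flat = np.ravel_multi_index(cols, shape)
            counts = np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape).astype(float)
        post = counts + alpha
        table = post / post.sum(axis=-1, keepdims=True)
        cpts[node] = Cpt(node, parents, table, pseudocount=alpha)
    return FittedNetwork(schema, structure, cpts, equivalent_sample_size)


def loglikelihood(network: FittedNetwork, cohort: Cohort) -> float:
    """Sum over rows of the log joint probability under the network.

    Decomposes as a sum of per-node log CPT entries.  If a row hits a
    zero-probability CPT cell (possible only with pseudocount 0) the result
    is ``-inf``, which is the distinct flag for an impossible record.
    """
    if cohort.schema.names != network.schema.names:
        raise SchemaMismatchError("cohort schema differs from network schema")
    total = 0.0
    for node, cpt in network.cpts.items():
        cols = [cohort.column(p) for p in cpt.parents] + [cohort.column(node)]
        probs = cpt.table[tuple(cols)]
        if (probs == 0).any():
            return float("-inf")
        total += float(np.log(probs).sum())
    return total
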