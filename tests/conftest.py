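"""Shared fixtures: tiny hand-built networks, random network factories,
and a cached default ground-truth generator."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from afrelapse import (
    Cohort,
    Cpt,
    DomainSchema,
    FittedNetwork,
    NetworkStructure,
    VariableSpec,
    build_default_schema,
    default_ground_truth,
)


@pytest.fixture(scope="session")
def schema() -> DomainSchema:
    return build_default_schema()


@pytest.fixture(scope="session")
def ground_truth():
    return default_ground_truth()


@pytest.fixture
def two_node_network() -> FittedNetwork:
    """A -> B with P(A=t)=0.3, P(B=t|A=t)=0.9, P(B=t|A=f)=0.2."""
    sch = DomainSchema(
        variables=(
            VariableSpec("a", ("false", "true")),
            VariableSpec("b", ("false", "true")),
        ),
        outcome_name="b",
    )
    structure = NetworkStructure(nodes=("a", "b"), arcs=frozenset({("a", "b")}))
    cpts = {
        "a": Cpt("a", (), np.array([0.7, 0.3])),
        "b": Cpt("b", ("a",), np.array([[0.8, 0.2], [0.1, 0.9]])),
    }
    return FittedNetwork(sch, structure, cpts)


def make_random_network(
    rng: np.random.Generator, n_nodes: int, max_card: int = 3, edge_prob: float = 0.4
) -> FittedNetwork:
    """Random DAG over ``n_nodes`` variables with Dirichlet-random CPTs."""
    names = tuple(f"v{i}" for i in range(n_nodes))
    cards = rng.integers(2, max_card + 1, size=n_nodes)
    sch = DomainSchema(
        variables=tuple(
            VariableSpec(n, tuple(f"s{k}" for k in range(c)))
            for n, c in zip(names, cards)
        ),
        outcome_name=names[-1],
    )
    order = rng.permutation(n_nodes)
    arcs = set()
    for i_pos, i in enumerate(order):
        for j in order[i_pos + 1 :]:
            if rng.random() < edge_prob:
                arcs.add((names[i], names[j]))
    structure = NetworkStructure(nodes=names, arcs=frozenset(arcs))
    cpts = {}
    for node in names:
        parents = structure.parents(node)
        shape = tuple(sch[p].cardinality for p in parents) + (sch[node].cardinality,)
        table = rng.dirichlet(np.ones(shape[-1]) * 2.0, size=shape[:-1] or (1,))
        if not parents:
            table = table[0]
        cpts[node] = Cpt(node, parents, table.reshape(shape))
    return FittedNetwork(sch, structure, cpts)


def brute_force_joint(network: FittedNetwork) -> dict[tuple[int, ...], float]:
    """Joint distribution by explicit per-cell CPT lookups (test oracle).

    Pure-python traversal, independent of the package's tensor machinery.
    """
    sch = network.schema
    cells = {}
    for assignment in itertools.product(*(range(c) for c in sch.cardinalities)):
        by_name = dict(zip(sch.names, assignment))
        p = 1.0
        for node, cpt in network.cpts.items():
            idx = tuple(by_name[par] for par in cpt.parents) + (by_name[node],)
            p *= float(cpt.table[idx])
        cells[assignment] = p
    return cells


def sample_from_network(
    network: FittedNetwork, n: int, rng: np.random.Generator
) -> Cohort:
    """Ancestral sampling used by tests (independent of the package's
    synthetic generator)."""
    sch = network.schema
    codes = np.zeros((n, len(sch.variables)), dtype=np.int64)
    for node in network.structure.topological_order():
        cpt = network.cpts[node]
        j = sch.index(node)
        for i in range(n):
            idx = tuple(codes[i, sch.index(p)] for p in cpt.parents)
            codes[i, j] = rng.choice(cpt.child_cardinality, p=cpt.table[idx])
    return Cohort(sch, codes)
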