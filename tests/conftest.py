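"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from anatomod.ontology import AnnotationTable, ICTable, OntologyGraph
from anatomod.network import WeightedNetwork


# ---------------------------------------------------------------------------
# ontology fixtures

def make_ontology(edges: list[tuple[str, str, str]],
                  names: dict[str, str] | None = None) -> OntologyGraph:
    """Build an OntologyGraph from (child, parent, relation) triples."""
    g = nx.MultiDiGraph()
    nodes = {e[0] for e in edges} | {e[1] for e in edges}
    g.add_nodes_from(nodes)
    for child, parent, rel in edges:
        g.add_edge(child, parent, key=rel)
    return OntologyGraph(graph=g, names=names or {})


@pytest.fixture
def chain_ontology() -> OntologyGraph:
    """root <- A <- {B, C} over is_a."""
    return make_ontology([
        ("A", "root", "is_a"),
        ("B", "A", "is_a"),
        ("C", "A", "is_a"),
    ])


@pytest.fixture
def chain_ic() -> ICTable:
    """Hand-injected IC values for the chain fixture."""
    return ICTable(
        ic={"root": 0.0, "A": 1.0, "B": 2.0, "C": 1.5},
        counts={"root": 10, "A": 4, "B": 1, "C": 2},
        total=10,
        constant=1.0,
    )


def random_dag(rng: np.random.Generator, n_terms: int,
               relations=("is_a", "part_of")) -> OntologyGraph:
    """Random rooted DAG: each non-root term gets 1-3 parents among earlier
    terms with a random relation type; term 0 is the root."""
    g = nx.MultiDiGraph()
    terms = [f"T{i}" for i in range(n_terms)]
    g.add_nodes_from(terms)
    for i in range(1, n_terms):
        n_parents = int(rng.integers(1, min(3, i) + 1))
        parents = rng.choice(i, size=n_parents, replace=False)
        for p in parents:
            rel = relations[rng.integers(0, len(relations))]
            g.add_edge(terms[i], terms[int(p)], key=rel)
    return OntologyGraph(graph=g)


def dfs_ancestors_oracle(g: OntologyGraph, term: str, relations) -> set[str]:
    """Independent recursive-DFS reflexive closure used to check `ancestors`."""
    rels = set(relations)
    out: set[str] = set()

    def visit(t: str) -> None:
        if t in out:
            return
        out.add(t)
        for _, parent, rel in g.graph.out_edges(t, keys=True):
            if rel in rels:
                visit(parent)

    visit(term)
    return out


def random_annotations(rng: np.random.Generator, g: OntologyGraph,
                       n_proteins: int = 20) -> AnnotationTable:
    terms = sorted(g.terms)
    pairs = []
    for i in range(n_proteins):
        k = int(rng.integers(1, 3))
        for t in rng.choice(len(terms), size=k, replace=False):
            pairs.append((f"P{i}", terms[int(t)]))
    return AnnotationTable.from_pairs(pairs)


# ---------------------------------------------------------------------------
# network fixtures

def make_network(edges: list[tuple[str, str, float]],
                 extra_nodes: tuple[str, ...] = ()) -> WeightedNetwork:
    net = WeightedNetwork()
    for u, v, w in edges:
        net.add_edge(u, v, w)
    net.graph.add_nodes_from(extra_nodes)
    return net


def random_network(rng: np.random.Generator, n: int = 50,
                   p: float = 0.15) -> WeightedNetwork:
    net = WeightedNetwork()
    nodes = [f"N{i}" for i in range(n)]
    net.graph.add_nodes_from(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(nodes[i], nodes[j], float(rng.random()))
    return net


# ---------------------------------------------------------------------------
# statistical oracles

def mann_whitney_auc_oracle(positives, negatives) -> float:
    """AUC as the Mann–Whitney pair-count statistic (ties count 1/2)."""
    wins = 0.0
    for p in positives:
        for q in negatives:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(positives) * len(negatives))


def exact_wilcoxon_oracle(x, y, alternative="two_sided") -> float:
    """Exhaustive-permutation two-sample rank-sum p-value (tie-free data)."""
    from itertools import combinations

    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)
    observed = sum(ranks[v] for v in x)
    sums = [sum(combo) for combo in combinations(range(1, len(pooled) + 1), n1)]
    total = len(sums)
    ge = sum(1 for s in sums if s >= observed) / total
    le = sum(1 for s in sums if s <= observed) / total
    if alternative == "greater":
        return ge
    if alternative == "less":
        return le
    return min(1.0, 2.0 * min(ge, le))


def hypergeom_tail_oracle(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail P(X >= k) by integer-binomial enumeration."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(n, K) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom
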