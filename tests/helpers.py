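"""Shared test helpers: tiny ontology builders and independent oracles.

The oracles here deliberately avoid the package's own closure, MICA and
ROC code paths: reachability comes from networkx, AUC from pairwise
Mann–Whitney counting, so that agreement is a genuine cross-check.
"""

from __future__ import annotations

import math

import networkx as nx

from phenomatch import Ontology, Term


def make_ontology(edges: dict[str, list[str]], species: str = "test") -> Ontology:
    """Build an ontology from ``{term: [parents...]}``."""
    return Ontology(
        [Term(t, f"label {t}", frozenset(ps)) for t, ps in edges.items()],
        species=species,
    )


def nx_parent_graph(edges: dict[str, list[str]]) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(edges)
    for child, parents in edges.items():
        for p in parents:
            g.add_edge(child, p)  # child -> parent
    return g


def nx_ancestors(edges: dict[str, list[str]], term: str) -> set[str]:
    """Reflexive ancestor set by graph reachability (independent oracle)."""
    g = nx_parent_graph(edges)
    return {term} | nx.descendants(g, term)


def brute_force_mica_score(
    edges: dict[str, list[str]], ic: dict[str, float], t1: str, t2: str
) -> float:
    """Exhaustive simJ × max-IC-common-ancestor geometric mean."""
    a1, a2 = nx_ancestors(edges, t1), nx_ancestors(edges, t2)
    simj = len(a1 & a2) / len(a1 | a2)
    covered = [ic[t] for t in (a1 & a2) if t in ic]
    assert covered, "oracle: no covered common ancestor"
    return math.sqrt(simj * max(covered))


def mann_whitney_auc(scores, labels) -> float:
    """Pairwise AUC: P(pos > neg) + 0.5 * P(pos == neg), by enumeration."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    assert pos and neg
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_dag_edges(rng, n_terms: int, max_parents: int = 3) -> dict[str, list[str]]:
    """Random rooted DAG in the {term: parents} form used by make_ontology."""
    edges: dict[str, list[str]] = {"T0": []}
    for i in range(1, n_terms):
        k = min(i, int(rng.integers(1, max_parents + 1)))
        parents = rng.choice(i, size=k, replace=False)
        edges[f"T{i}"] = [f"T{j}" for j in sorted(parents.tolist())]
    return edges
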