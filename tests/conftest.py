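"""Shared fixtures and independent oracles.

The oracles deliberately take different routes from the library code:
networkx shortest paths for patristic distances, explicit enumeration of
internal-state assignments for parsimony lengths, and generic numeric
minimisation for least-squares scores.
"""

from __future__ import annotations

from itertools import product

import networkx as nx
import numpy as np
import pytest
from scipy.optimize import minimize

from hennig import CharacterMatrix, RootedTree
from hennig.datasets import conflict_matrix


@pytest.fixture
def conflict5() -> CharacterMatrix:
    """Five taxa, three pairwise-conflicting characters, outgroup O."""
    return conflict_matrix()


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def tree_graph(tree: RootedTree, use_lengths: bool = False) -> nx.Graph:
    graph = nx.Graph()
    for node in tree.preorder():
        if node.parent is not None:
            graph.add_edge(id(node.parent), id(node),
                           weight=node.length if use_lengths else 1.0)
    return graph


def oracle_path_length(tree: RootedTree, a: str, b: str,
                       use_lengths: bool = False) -> float:
    graph = tree_graph(tree, use_lengths)
    ids = {n.label: id(n) for n in tree.leaves()}
    return nx.shortest_path_length(graph, ids[a], ids[b], weight="weight")


def oracle_parsimony_length(tree: RootedTree, column: dict[str, str | None],
                            states: list[str],
                            ordered: bool = False) -> int:
    """Minimal steps by enumerating every internal (and missing-leaf)
    state assignment.  Exponential; only for tiny trees."""
    nodes = list(tree.preorder())
    free = [n for n in nodes
            if not n.is_leaf or column.get(n.label) is None]
    fixed = {id(n): column[n.label] for n in nodes
             if n.is_leaf and column.get(n.label) is not None}

    def cost(assign: dict[int, str]) -> int:
        total = 0
        for node in nodes:
            if node.parent is None:
                continue
            a = assign.get(id(node), fixed.get(id(node)))
            b = assign.get(id(node.parent), fixed.get(id(node.parent)))
            if ordered:
                total += abs(int(a) - int(b))
            elif a != b:
                total += 1
        return total

    best = None
    for combo in product(states, repeat=len(free)):
        assign = {id(n): s for n, s in zip(free, combo)}
        c = cost(assign)
        if best is None or c < best:
            best = c
    return best


def oracle_ols_score(tree: RootedTree, taxa: list[str], d: np.ndarray,
                     w: np.ndarray | None = None) -> float:
    """Least-squares score by generic numeric minimisation over branch
    lengths (unconstrained), independent of the linear-algebra route."""
    edges = [n for n in tree.preorder() if n.parent is not None]
    leaves = {n.label: n for n in tree.leaves()}
    n = len(taxa)
    if w is None:
        w = np.ones((n, n))

    # fixed leaf-to-leaf edge paths from networkx (topology is constant;
    # lengths may go negative during the search, so paths are found once on
    # the unweighted graph and summed manually)
    graph = nx.Graph()
    for k, node in enumerate(edges):
        graph.add_edge(id(node.parent), id(node), index=k)
    pair_paths = []
    iu = np.triu_indices(n, 1)
    for i, j in zip(*iu):
        path = nx.shortest_path(graph, id(leaves[taxa[i]]),
                                id(leaves[taxa[j]]))
        pair_paths.append([graph.edges[u, v]["index"]
                           for u, v in zip(path, path[1:])])

    def objective(lengths: np.ndarray) -> float:
        total = 0.0
        for (i, j), path in zip(zip(*iu), pair_paths):
            p = sum(lengths[k] for k in path)
            total += w[i, j] * (d[i, j] - p) ** 2
        return float(total)

    # the objective is convex quadratic in the lengths, so quasi-Newton
    # minimisation from a generic start is an exact independent check
    x0 = np.ones(len(edges))
    res = minimize(objective, x0, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 10000})
    res2 = minimize(objective, res.x, method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-14,
                             "maxiter": 5000})
    return float(min(res.fun, res2.fun))


def double_factorial(k: int) -> int:
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out
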