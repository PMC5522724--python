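"""Tree estimation from distance tables.

Branch lengths for a fixed topology are fitted by (weighted) least squares
over the path-indicator linear system; the score of a topology is the
minimised weighted sum of squared deviations.  Topology search is exhaustive
over unrooted binary trees up to a configurable size, and neighbour-joining
plus NNI hill-climbing beyond it.  Balanced minimum evolution lengths use
the closed-form topological weighting 2**(1 - t_ij).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from scipy.optimize import nnls

from .model import (DistanceTable, FitResult, HennigError, Node, RootedTree,
                    TreeError, leaf)

CRITERIA = ("ols", "wls", "bme")
NEGBRLEN_POLICIES = ("allow", "clamp_zero", "constrain_nonneg")


@dataclass
class FitConfig:
    """Options controlling branch-length fitting and topology search.

    ``power`` is the exponent P' of the distance-power weights
    ``w_ij = d_ij ** -P'`` (0 means unweighted).
    """

    criterion: str = "ols"
    power: float = 0.0
    negbrlen: str = "allow"
    search: str = "auto"  # auto | exhaustive | nni
    exhaustive_limit: int = 8
    tie_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.power < 0:
            raise ValueError("weight power P' must be non-negative")
        if self.negbrlen not in NEGBRLEN_POLICIES:
            raise ValueError(f"unknown negbrlen policy {self.negbrlen!r}")
        if self.exhaustive_limit < 4:
            raise ValueError("exhaustive_limit must be at least 4")
        if self.criterion == "ols":
            self.power = 0.0


# ---------------------------------------------------------------------------
# Unrooted topology plumbing (leaves are 0..n-1, internal nodes >= n)
# ---------------------------------------------------------------------------

Edge = tuple[int, int]


def enumerate_unrooted_topologies(n: int) -> Iterator[list[Edge]]:
    """Yield the (2n-5)!! unrooted binary topologies as edge lists."""
    if n < 3:
        raise HennigError("need at least 3 taxa")
    base = [(n, 0), (n, 1), (n, 2)]

    def rec(edges: list[Edge], next_leaf: int, next_internal: int):
        if next_leaf == n:
            yield edges
            return
        for k in range(len(edges)):
            u, v = edges[k]
            w = next_internal
            grown = edges[:k] + edges[k + 1:] + [(u, w), (w, v),
                                                 (w, next_leaf)]
            yield from rec(grown, next_leaf + 1, next_internal + 1)

    yield from rec(base, 3, n + 1)


def _edge_masks(edges: Sequence[Edge], n: int) -> list[int]:
    """Per-edge leaf bitmask of the side *not* containing leaf 0, aligned
    with ``edges``."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    below: dict[int, int] = {}

    order: list[tuple[int, int]] = []  # (node, parent) in DFS preorder
    stack = [(0, -1)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    for node, parent in reversed(order):
        mask = (1 << node) if node < n else 0
        for nb in adj[node]:
            if nb != parent:
                mask |= below[nb]
        below[node] = mask

    child_of = {}
    for node, parent in order:
        if parent >= 0:
            child_of[frozenset((node, parent))] = node
    return [below[child_of[frozenset(e)]] for e in edges]


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iidx, jidx = np.triu_indices(n, k=1)
    return iidx, jidx


def _design_matrix(masks: Sequence[int], n: int,
                   iidx: np.ndarray, jidx: np.ndarray) -> np.ndarray:
    bits = (np.asarray(masks, dtype=np.uint64)[:, None]
            >> np.arange(n, dtype=np.uint64)) & 1
    return (bits[:, iidx] != bits[:, jidx]).T.astype(float)


def _condensed(table: DistanceTable,
               iidx: np.ndarray, jidx: np.ndarray) -> np.ndarray:
    return table.d[iidx, jidx]


def _weights(dvec: np.ndarray, power: float) -> np.ndarray:
    if power == 0:
        return np.ones_like(dvec)
    if np.any(dvec == 0):
        raise HennigError(
            "zero distance is incompatible with P' > 0 exponential weights")
    return dvec ** (-power)


def _solve_ls(A: np.ndarray, dvec: np.ndarray, w: np.ndarray,
              policy: str) -> tuple[np.ndarray, np.ndarray, float]:
    sw = np.sqrt(w)
    Aw = A * sw[:, None]
    dw = dvec * sw
    if policy == "constrain_nonneg":
        b, _ = nnls(Aw, dw)
    else:
        b, *_ = np.linalg.lstsq(Aw, dw, rcond=None)
        if policy == "clamp_zero":
            b = np.maximum(b, 0.0)
    p = A @ b
    score = float(np.sum(w * (dvec - p) ** 2))
    return b, p, score


def _square(pvec: np.ndarray, n: int, iidx: np.ndarray,
            jidx: np.ndarray) -> np.ndarray:
    out = np.zeros((n, n))
    out[iidx, jidx] = pvec
    out[jidx, iidx] = pvec
    return out


def _edges_to_tree(edges: Sequence[Edge], lengths: Sequence[float],
                   labels: Sequence[str]) -> RootedTree:
    """Materialise an edge list as a RootedTree (arbitrary internal root)."""
    n = len(labels)
    length_of = {frozenset(e): float(x) for e, x in zip(edges, lengths)}
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root_id = next(i for i in sorted(adj) if i >= n)
    nodes: dict[int, Node] = {}

    def build(i: int, parent: int) -> Node:
        node = leaf(labels[i]) if i < n else Node()
        nodes[i] = node
        if parent >= 0:
            node.length = length_of[frozenset((i, parent))]
        for nb in adj[i]:
            if nb != parent:
                node.add_child(build(nb, i))
        return node

    return RootedTree(build(root_id, -1), rooted=False, validate=False)


def _tree_to_edges(tree: RootedTree,
                   taxa: Sequence[str]) -> tuple[list[Edge], list[float]]:
    """Edge list of a tree viewed as an unrooted graph (degree-2 root
    merged away); leaf ids follow ``taxa`` order."""
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    ids: dict[int, int] = {}
    next_internal = n
    edges: list[Edge] = []
    lengths: list[float] = []
    for node in tree.preorder():
        if node.is_leaf:
            if node.label not in index:
                raise TreeError(f"leaf {node.label!r} not in taxa")
            ids[id(node)] = index[node.label]
        else:
            ids[id(node)] = next_internal
            next_internal += 1
    for node in tree.preorder():
        if node is tree.root:
            continue
        edges.append((ids[id(node.parent)], ids[id(node)]))
        lengths.append(node.length)
    if len(tree.root.children) == 2:
        # merge the two root edges into the single unrooted edge they form
        a, b = tree.root.children
        ra, rb = ids[id(tree.root)], None
        merged: list[Edge] = []
        merged_len: list[float] = []
        for (u, v), ln in zip(edges, lengths):
            if u == ids[id(tree.root)]:
                continue
            merged.append((u, v))
            merged_len.append(ln)
        merged.append((ids[id(a)], ids[id(b)]))
        merged_len.append(a.length + b.length)
        edges, lengths = merged, merged_len
    return edges, lengths


# ---------------------------------------------------------------------------
# Fitting a fixed topology
# ---------------------------------------------------------------------------


def ols_fit(topology: RootedTree, table: DistanceTable,
            config: Optional[FitConfig] = None) -> FitResult:
    """Fit branch lengths to ``topology`` by (weighted) least squares.

    The topology's leaf set must equal the table's taxa.  Every edge of the
    tree as drawn (including both root edges of a bifurcating root, which
    share a path-indicator column) receives a fitted length; the reported
    score is the minimised weighted sum of squared deviations.
    """
    config = config or FitConfig()
    taxa = table.taxa
    if set(topology.leaf_labels()) != set(taxa):
        raise TreeError("topology leaf set differs from table taxa")
    n = len(taxa)
    iidx, jidx = _pair_indices(n)
    dvec = _condensed(table, iidx, jidx)
    w = _weights(dvec, config.power)

    fitted = topology.copy()
    index = {t: i for i, t in enumerate(taxa)}
    nodes = [nd for nd in fitted.preorder() if nd is not fitted.root]
    masks = []
    below: dict[int, int] = {}
    for nd in fitted.postorder():
        if nd.is_leaf:
            below[id(nd)] = 1 << index[nd.label]
        else:
            below[id(nd)] = 0
            for c in nd.children:
                below[id(nd)] |= below[id(c)]
    masks = [below[id(nd)] for nd in nodes]
    A = _design_matrix(masks, n, iidx, jidx)
    b, pvec, score = _solve_ls(A, dvec, w, config.negbrlen)
    for nd, x in zip(nodes, b):
        nd.length = float(x)
    criterion = "wls" if config.power > 0 else "ols"
    return FitResult(tree=fitted, score=score, criterion=criterion,
                     taxa=tuple(taxa), p=_square(pvec, n, iidx, jidx),
                     config=config)


def bme_length(topology: RootedTree, table: DistanceTable) -> float:
    """Balanced minimum-evolution length: sum of 2**(1 - t_ij) * d_ij over
    pairs, where t_ij is the number of edges on the i-j path.  Requires a
    binary (fully resolved) unrooted topology."""
    taxa = table.taxa
    if set(topology.leaf_labels()) != set(taxa):
        raise TreeError("topology leaf set differs from table taxa")
    n = len(taxa)
    edges, _ = _tree_to_edges(topology, taxa)
    if len(edges) != 2 * n - 3:
        raise TreeError("BME requires a fully resolved (binary) topology")
    iidx, jidx = _pair_indices(n)
    masks = _edge_masks(edges, n)
    A = _design_matrix(masks, n, iidx, jidx)
    t = A.sum(axis=1)
    dvec = _condensed(table, iidx, jidx)
    return float(np.sum(dvec * np.exp2(1.0 - t)))


# ---------------------------------------------------------------------------
# Topology search
# ---------------------------------------------------------------------------


def _score_edges(edges: Sequence[Edge], n: int, dvec: np.ndarray,
                 w: np.ndarray, iidx: np.ndarray, jidx: np.ndarray,
                 config: FitConfig):
    masks = _edge_masks(edges, n)
    A = _design_matrix(masks, n, iidx, jidx)
    if config.criterion == "bme":
        t = A.sum(axis=1)
        score = float(np.sum(dvec * np.exp2(1.0 - t)))
        b, pvec, _ = _solve_ls(A, dvec, w, config.negbrlen)
    else:
        b, pvec, score = _solve_ls(A, dvec, w, config.negbrlen)
    return score, b, pvec


def _nni_neighbors(edges: list[Edge], n: int) -> Iterator[list[Edge]]:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    eset = {frozenset(e) for e in edges}
    for u, v in edges:
        if u < n or v < n:
            continue  # internal edges only
        a_side = [x for x in adj[u] if x != v]
        b_side = [x for x in adj[v] if x != u]
        for bx in range(len(b_side)):
            # swap a_side[1] with b_side[bx]
            swapped = set(eset)
            swapped.discard(frozenset((u, a_side[1])))
            swapped.discard(frozenset((v, b_side[bx])))
            swapped.add(frozenset((u, b_side[bx])))
            swapped.add(frozenset((v, a_side[1])))
            yield [tuple(sorted(e)) for e in swapped]


def search_best_tree(table: DistanceTable,
                     config: Optional[FitConfig] = None,
                     outgroup: Optional[str] = None) -> list[FitResult]:
    """Find the optimal topology(ies) for a distance table.

    Exhaustive enumeration of unrooted binary topologies when the taxon
    count is within ``config.exhaustive_limit`` (or ``search='exhaustive'``);
    otherwise a neighbour-joining start followed by NNI hill-climbing.  All
    topologies whose score is within ``tie_tolerance`` of the optimum are
    returned, best first.  If ``outgroup`` is given the result trees are
    rooted on its pendant edge.
    """
    config = config or FitConfig()
    taxa = table.taxa
    n = len(taxa)
    if n < 4:
        raise HennigError("topology search requires at least 4 taxa")
    iidx, jidx = _pair_indices(n)
    dvec = _condensed(table, iidx, jidx)
    w = _weights(dvec, config.power)

    exhaustive = (config.search == "exhaustive"
                  or (config.search == "auto"
                      and n <= config.exhaustive_limit))

    best: list[tuple[float, list[Edge], np.ndarray, np.ndarray]] = []
    best_score = np.inf
    tol = config.tie_tolerance

    def consider(edges: list[Edge]) -> float:
        nonlocal best_score, best
        score, b, pvec = _score_edges(edges, n, dvec, w, iidx, jidx, config)
        if score < best_score - tol:
            best_score = score
            best = [(score, list(edges), b, pvec)]
        elif score <= best_score + tol:
            keys = {_topology_signature(e, n) for _, e, _, _ in best}
            if _topology_signature(edges, n) not in keys:
                best.append((score, list(edges), b, pvec))
        return score

    if exhaustive:
        for edges in enumerate_unrooted_topologies(n):
            consider(edges)
    else:
        start = nj_tree(table)
        edges, _ = _tree_to_edges(start, taxa)
        current = [tuple(sorted(e)) for e in edges]
        current_score = consider(current)
        improved = True
        while improved:
            improved = False
            for neighbor in list(_nni_neighbors(current, n)):
                score = consider(neighbor)
                if score < current_score - tol:
                    current, current_score = neighbor, score
                    improved = True
                    break

    results = []
    for score, edges, b, pvec in sorted(best, key=lambda x: x[0]):
        if score > best_score + tol:
            continue
        tree = _edges_to_tree(edges, b, taxa)
        if outgroup is not None:
            tree = root_at_outgroup(tree, outgroup)
        criterion = config.criterion if config.criterion == "bme" else (
            "wls" if config.power > 0 else "ols")
        results.append(FitResult(tree=tree, score=score, criterion=criterion,
                                 taxa=tuple(taxa),
                                 p=_square(pvec, n, iidx, jidx),
                                 config=config))
    return results


def _topology_signature(edges: Sequence[Edge], n: int) -> frozenset:
    masks = _edge_masks(edges, n)
    full = (1 << n) - 1
    out = set()
    for m in masks:
        side = m if not (m & 1) else (~m) & full
        if bin(side).count("1") > 1:
            out.add(side)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Agglomerative methods
# ---------------------------------------------------------------------------


def nj_tree(table: DistanceTable) -> RootedTree:
    """Saitou-Nei neighbour joining; deterministic tie-break on the
    lexicographically smallest label pair.  The result is unrooted (root
    placement arbitrary); branch lengths may be negative."""
    n = table.ntax
    if n < 3:
        raise HennigError("neighbour joining requires at least 3 taxa")
    nodes: dict[int, Node] = {i: leaf(t) for i, t in enumerate(table.taxa)}
    keys: dict[int, str] = {i: t for i, t in enumerate(table.taxa)}
    D: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[frozenset((i, j))] = float(table.d[i, j])
    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[frozenset((i, j))] for j in active if j != i)
             for i in active}
        best_pair, best_q, best_key = None, np.inf, None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * D[frozenset((i, j))] - r[i] - r[j]
                key = tuple(sorted((keys[i], keys[j])))
                if (q < best_q - 1e-12
                        or (abs(q - best_q) <= 1e-12 and key < best_key)):
                    best_pair, best_q, best_key = (i, j), q, key
        i, j = best_pair
        dij = D[frozenset((i, j))]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[next_id] = parent
        keys[next_id] = min(keys[i], keys[j])
        for k in active:
            if k in (i, j):
                continue
            D[frozenset((next_id, k))] = (
                D[frozenset((i, k))] + D[frozenset((j, k))] - dij) / 2
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    a, b, c = active
    dab = D[frozenset((a, b))]
    dac = D[frozenset((a, c))]
    dbc = D[frozenset((b, c))]
    nodes[a].length = (dab + dac - dbc) / 2
    nodes[b].length = (dab + dbc - dac) / 2
    nodes[c].length = (dac + dbc - dab) / 2
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    return RootedTree(root, rooted=False, validate=False)


def upgma_tree(table: DistanceTable) -> RootedTree:
    """Average-linkage (UPGMA) ultrametric tree with deterministic
    lexicographic tie-breaking."""
    n = table.ntax
    if n < 2:
        raise HennigError("UPGMA requires at least 2 taxa")
    nodes: dict[int, Node] = {i: leaf(t) for i, t in enumerate(table.taxa)}
    height = {i: 0.0 for i in range(n)}
    size = {i: 1 for i in range(n)}
    keys = {i: t for i, t in enumerate(table.taxa)}
    D: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[frozenset((i, j))] = float(table.d[i, j])
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        best_pair, best_d, best_key = None, np.inf, None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                d = D[frozenset((i, j))]
                key = tuple(sorted((keys[i], keys[j])))
                if (d < best_d - 1e-12
                        or (abs(d - best_d) <= 1e-12 and key < best_key)):
                    best_pair, best_d, best_key = (i, j), d, key
        i, j = best_pair
        h = best_d / 2
        parent = Node()
        nodes[i].length = h - height[i]
        nodes[j].length = h - height[j]
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[next_id] = parent
        height[next_id] = h
        size[next_id] = size[i] + size[j]
        keys[next_id] = min(keys[i], keys[j])
        for k in active:
            if k in (i, j):
                continue
            D[frozenset((next_id, k))] = (
                size[i] * D[frozenset((i, k))]
                + size[j] * D[frozenset((j, k))]) / (size[i] + size[j])
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return RootedTree(nodes[active[0]], rooted=True, validate=False)


# ---------------------------------------------------------------------------
# Consensus and rooting
# ---------------------------------------------------------------------------


def strict_consensus(trees: Sequence[RootedTree]) -> RootedTree:
    """Rooted strict consensus: exactly the clades present in every tree."""
    trees = list(trees)
    if not trees:
        raise HennigError("no trees to take a consensus of")
    universe = frozenset(trees[0].leaf_labels())
    for t in trees[1:]:
        if frozenset(t.leaf_labels()) != universe:
            raise TreeError("strict consensus requires identical leaf sets")
    common = set(trees[0].clades())
    for t in trees[1:]:
        common &= t.clades()
    common.discard(universe)
    common = {c for c in common if len(c) > 1}

    rank = {label: i for i, label in enumerate(trees[0].leaf_labels())}
    by_size = sorted(common, key=len)
    node_of = {c: Node() for c in by_size}
    root = Node()

    def smallest_container(s: frozenset) -> Node:
        for c in by_size:
            if len(c) > len(s) and s <= c:
                return node_of[c]
        return root

    for c in sorted(common, key=len, reverse=True):
        smallest_container(c).add_child(node_of[c])
    for label in sorted(universe, key=rank.get):
        smallest_container(frozenset([label])).add_child(leaf(label))

    def sort_children(node: Node) -> int:
        if node.is_leaf:
            return rank[node.label]
        firsts = [sort_children(c) for c in node.children]
        order = np.argsort(firsts, kind="stable")
        node.children = [node.children[i] for i in order]
        return min(firsts)

    sort_children(root)
    return RootedTree(root, rooted=True)


def root_at_outgroup(tree: RootedTree, outgroup: str) -> RootedTree:
    """Root (or re-root) a tree on the outgroup's pendant edge, yielding
    ``(outgroup, (everything else))``.  Already-rooted input in that form is
    returned unchanged (up to copying)."""
    t = tree.copy()
    target = None
    for node in t.preorder():
        if node.label == outgroup:
            target = node
            break
    if target is None:
        raise TreeError(f"outgroup {outgroup!r} is not in the tree")
    if not target.is_leaf:
        raise TreeError(f"outgroup {outgroup!r} is not a leaf")
    parent = target.parent
    if parent is None:
        raise TreeError("cannot root a single-leaf tree")
    if parent is t.root and len(parent.children) == 2:
        return RootedTree(t.root, rooted=True, validate=False)

    # detach the outgroup, reorient the rest at its former parent, and hang
    # both under a fresh root
    path = []
    cur = parent
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    saved = [nd.length for nd in path]
    parent.children.remove(target)
    for idx in range(len(path) - 1):
        child, up = path[idx], path[idx + 1]
        up.children.remove(child)
        child.add_child(up)
        up.length = saved[idx]
    parent.parent = None

    new_root = Node()
    new_root.add_child(target)
    parent.length = 0.0
    new_root.add_child(parent)
    _suppress_unary(new_root)
    return RootedTree(new_root, rooted=True, validate=False)


def _suppress_unary(root: Node) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        changed = True
        while changed:
            changed = False
            for i, child in enumerate(node.children):
                if not child.is_leaf and len(child.children) == 1:
                    grand = child.children[0]
                    grand.length += child.length
                    grand.parent = node
                    node.children[i] = grand
                    changed = True
        stack.extend(node.children)
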