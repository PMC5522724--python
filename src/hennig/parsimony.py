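"""Parsimony scoring used to verify the distance pipeline: Fitch (unordered)
and linear-cost (ordered) step counts, ensemble CI/RI, and a small
most-parsimonious-tree search.

Missing entries ('?', gaps, ambiguity codes) contribute no constraint.
Step counting is exact on polytomies (Hartigan's generalisation of Fitch
for unordered characters; Sankoff dynamic programming with linear costs
for ordered ones).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import (MISSING, CharacterMatrix, HennigError, MatrixError,
                    RootedTree, TreeError)
from .treefit import (_edges_to_tree, _nni_neighbors,
                      enumerate_unrooted_topologies)

_DNA_MAP = {"A": "A", "C": "C", "G": "G", "T": "T", "U": "T"}


def _symbol_to_state(symbol: str, alphabet: str) -> Optional[str]:
    """Canonical state symbol, or None when the cell carries no constraint."""
    if symbol == MISSING:
        return None
    if alphabet == "dna":
        return _DNA_MAP.get(symbol.upper())
    return symbol


@dataclass
class ParsimonyResult:
    length: int
    ci: Optional[float]
    ri: Optional[float]
    trees: list[RootedTree] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Per-character machinery
# ---------------------------------------------------------------------------


class _Character:
    """One column prepared for scoring: per-taxon state-set bitmasks."""

    def __init__(self, column: Sequence[str], taxa: Sequence[str],
                 alphabet: str, ordered: bool):
        self.ordered = ordered
        observed: list[str] = []
        raw = {}
        for taxon, symbol in zip(taxa, column):
            state = _symbol_to_state(symbol, alphabet)
            raw[taxon] = state
            if state is not None and state not in observed:
                observed.append(state)
        if ordered:
            for s in observed:
                if not s.isdigit():
                    raise MatrixError(
                        f"ordered character has non-integer state {s!r}")
            values = sorted(int(s) for s in observed)
            self.lo = values[0] if values else 0
            self.hi = values[-1] if values else 0
            self.states = [str(v) for v in range(self.lo, self.hi + 1)]
        else:
            self.states = sorted(observed)
        self.index = {s: i for i, s in enumerate(self.states)}
        self.nstates = len(self.states)
        full = (1 << self.nstates) - 1
        self.mask = {t: (full if raw[t] is None
                         else 1 << self.index[raw[t]]) for t in taxa}
        self.counts = [0] * self.nstates
        for t in taxa:
            s = raw[t]
            if s is not None:
                self.counts[self.index[s]] += 1

    # -- conceivable step bounds (for CI/RI) --------------------------------

    def min_steps(self) -> int:
        present = [c for c in self.counts if c > 0]
        if not present:
            return 0
        if self.ordered:
            lo = min(i for i, c in enumerate(self.counts) if c > 0)
            hi = max(i for i, c in enumerate(self.counts) if c > 0)
            return hi - lo
        return len(present) - 1

    def max_steps(self) -> int:
        """Maximum steps on any tree (the star / worst-bush bound)."""
        scored = sum(self.counts)
        if scored == 0:
            return 0
        if self.ordered:
            total = 0
            for cut in range(self.nstates - 1):
                left = sum(self.counts[: cut + 1])
                total += min(left, scored - left)
            return total
        return scored - max(self.counts)


def _order_and_children(adj: dict[int, list[int]], root: int):
    order: list[int] = []
    children: dict[int, list[int]] = {}
    stack = [(root, -1)]
    while stack:
        node, parent = stack.pop()
        order.append(node)
        kids = [x for x in adj[node] if x != parent]
        children[node] = kids
        for k in kids:
            stack.append((k, node))
    return list(reversed(order)), children


def _char_length_unordered(char: _Character, order, children,
                           leafmask) -> int:
    sets: dict[int, int] = {}
    steps = 0
    for node in order:
        kids = children[node]
        if not kids:
            sets[node] = leafmask[node]
            continue
        best_count = 0
        best_set = 0
        for s in range(char.nstates):
            bit = 1 << s
            count = sum(1 for k in kids if sets[k] & bit)
            if count > best_count:
                best_count, best_set = count, bit
            elif count == best_count:
                best_set |= bit
        sets[node] = best_set
        steps += len(kids) - best_count
    return steps


def _char_length_ordered(char: _Character, order, children, leafmask) -> int:
    INF = float("inf")
    ns = char.nstates
    cost: dict[int, list[float]] = {}
    for node in order:
        kids = children[node]
        if not kids:
            mask = leafmask[node]
            cost[node] = [0.0 if (mask >> s) & 1 else INF
                          for s in range(ns)]
            continue
        acc = [0.0] * ns
        for k in kids:
            ck = cost[k]
            for s in range(ns):
                acc[s] += min(ck[t] + abs(s - t) for t in range(ns))
        cost[node] = acc
    return int(min(cost[order[-1]]))


# ---------------------------------------------------------------------------
# Public scoring
# ---------------------------------------------------------------------------


def _prepare_characters(matrix: CharacterMatrix,
                        ordered: Iterable[int]) -> list[_Character]:
    ordered_set = set(ordered)
    return [_Character(matrix.column(j), matrix.taxa, matrix.alphabet,
                       j in ordered_set)
            for j in range(matrix.nchar)]


def _tree_scaffold(tree: RootedTree, taxa: Sequence[str]):
    """Adjacency/postorder scaffold of a tree for repeated char scoring."""
    labels = tree.leaf_labels()
    missing = set(taxa) - set(labels)
    if missing:
        raise TreeError(f"matrix taxa absent from tree: {sorted(missing)}")
    adj: dict[int, list[int]] = {}
    label_of: dict[int, str] = {}
    ids: dict[int, int] = {}
    counter = 0
    for node in tree.preorder():
        ids[id(node)] = counter
        if node.is_leaf:
            label_of[counter] = node.label
        counter += 1
    for node in tree.preorder():
        adj.setdefault(ids[id(node)], [])
        if node.parent is not None:
            u, v = ids[id(node.parent)], ids[id(node)]
            adj[u].append(v)
            adj.setdefault(v, []).append(u)
    root = ids[id(tree.root)]
    order, children = _order_and_children(adj, root)
    return order, children, label_of


def tree_length(tree: RootedTree, matrix: CharacterMatrix,
                ordered: Iterable[int] = ()) -> int:
    """Minimal number of character-state changes of ``matrix`` on ``tree``.

    Unordered characters use Fitch/Hartigan counting; characters listed in
    ``ordered`` (0-based indices) use linear step costs.  Tree leaves not in
    the matrix are treated as all-missing.
    """
    chars = _prepare_characters(matrix, ordered)
    order, children, label_of = _tree_scaffold(tree, matrix.taxa)
    total = 0
    for char in chars:
        full = (1 << char.nstates) - 1
        leafmask = {node: char.mask.get(label, full)
                    for node, label in label_of.items()}
        if char.nstates == 0:
            continue
        if char.ordered:
            total += _char_length_ordered(char, order, children, leafmask)
        else:
            total += _char_length_unordered(char, order, children, leafmask)
    return total


def ci_ri(matrix: CharacterMatrix, length: int,
          ordered: Iterable[int] = ()) -> tuple[Optional[float],
                                                Optional[float]]:
    """Ensemble consistency and retention indices for an observed length.

    CI = (sum of per-character minima) / length; RI = (G - length)/(G - M)
    with G the sum of per-character maxima over all trees.  Undefined values
    (zero denominators) are reported as None.
    """
    chars = _prepare_characters(matrix, ordered)
    m_total = sum(c.min_steps() for c in chars)
    g_total = sum(c.max_steps() for c in chars)
    ci = m_total / length if length > 0 else None
    ri = ((g_total - length) / (g_total - m_total)
          if g_total > m_total else None)
    return ci, ri


def score_result(tree: RootedTree, matrix: CharacterMatrix,
                 ordered: Iterable[int] = ()) -> ParsimonyResult:
    length = tree_length(tree, matrix, ordered)
    ci, ri = ci_ri(matrix, length, ordered)
    return ParsimonyResult(length, ci, ri, [tree])


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------


def _length_on_edges(edges, n, chars, leafmasks) -> int:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    order, children = _order_and_children(adj, next(iter(adj)))
    total = 0
    for char, masks in zip(chars, leafmasks):
        if char.nstates == 0:
            continue
        if char.ordered:
            total += _char_length_ordered(char, order, children, masks)
        else:
            total += _char_length_unordered(char, order, children, masks)
    return total


def mp_search(matrix: CharacterMatrix, ordered: Iterable[int] = (),
              exhaustive_limit: int = 9, replicates: int = 10,
              seed: int = 0,
              outgroup: Optional[str] = None) -> ParsimonyResult:
    """Search for most parsimonious trees.

    Exhaustive over all unrooted topologies up to ``exhaustive_limit`` taxa
    (authoritative); beyond that, random-addition starts with NNI
    hill-climbing.  Returns the minimal length, ensemble CI/RI at that
    length, and the minimal trees found (rooted on the outgroup when one is
    designated).
    """
    taxa = matrix.taxa
    n = len(taxa)
    if n < 4:
        raise HennigError("parsimony search requires at least 4 taxa")
    chars = _prepare_characters(matrix, ordered)
    # leaf ids 0..n-1 in taxa order (matches enumerate_unrooted_topologies)
    full_of = [(1 << c.nstates) - 1 for c in chars]
    leafmasks = [{i: c.mask[t] for i, t in enumerate(taxa)} for c in chars]

    best_len = None
    best_edges: list[list] = []

    def consider(edges) -> int:
        nonlocal best_len, best_edges
        length = _length_on_edges(edges, n, chars, leafmasks)
        if best_len is None or length < best_len:
            best_len = length
            best_edges = [list(edges)]
        elif length == best_len:
            from .treefit import _topology_signature
            sigs = {_topology_signature(e, n) for e in best_edges}
            if _topology_signature(edges, n) not in sigs:
                best_edges.append(list(edges))
        return length

    if n <= exhaustive_limit:
        for edges in enumerate_unrooted_topologies(n):
            consider(edges)
    else:
        rng = random.Random(seed)
        for _ in range(replicates):
            order = list(range(n))
            rng.shuffle(order)
            edges = [(2 * n, order[0]), (2 * n, order[1]),
                     (2 * n, order[2])]
            next_internal = 2 * n + 1
            for leaf_id in order[3:]:
                best_insert, best_insert_len = None, None
                for k in range(len(edges)):
                    u, v = edges[k]
                    w = next_internal
                    trial = edges[:k] + edges[k + 1:] + [
                        (u, w), (w, v), (w, leaf_id)]
                    ln = _length_on_edges(trial, n, chars, leafmasks)
                    if best_insert_len is None or ln < best_insert_len:
                        best_insert, best_insert_len = trial, ln
                edges = best_insert
                next_internal += 1
            current = [tuple(sorted(e)) for e in edges]
            current_len = consider(current)
            improved = True
            while improved:
                improved = False
                for neighbor in _nni_neighbors(current, n):
                    ln = consider(neighbor)
                    if ln < current_len:
                        current, current_len = neighbor, ln
                        improved = True
                        break

    trees = []
    for edges in best_edges:
        tree = _edges_to_tree(edges, [1.0] * len(edges), list(taxa))
        if outgroup is not None or matrix.outgroup is not None:
            from .treefit import root_at_outgroup
            tree = root_at_outgroup(tree, outgroup or matrix.outgroup)
        trees.append(tree)
    ci, ri = ci_ri(matrix, best_len, ordered)
    return ParsimonyResult(best_len, ci, ri, trees)
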