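"""Deterministic generators for test data: random rooted trees, perfect
clade matrices read off a tree, reversal perturbations, and homoplasy-free
DNA alignments.
"""

from __future__ import annotations

import random
import string
from typing import Optional, Sequence

from .model import (CharacterMatrix, HennigError, Node, RootedTree, leaf)


def _default_labels(n: int) -> list[str]:
    out = []
    for i in range(n):
        if n <= 26:
            out.append(string.ascii_uppercase[i])
        else:
            out.append(f"T{i + 1}")
    return out


def random_rooted_tree(n: int, seed: int,
                       labels: Optional[Sequence[str]] = None) -> RootedTree:
    """A random binary rooted tree over ``n`` labelled leaves, built by
    sequential attachment to a uniformly chosen edge; reproducible per
    seed.  All edge lengths are unity."""
    if n < 3:
        raise HennigError("need at least 3 taxa")
    labels = list(labels) if labels is not None else _default_labels(n)
    if len(labels) != n:
        raise HennigError("label count must equal n")
    rng = random.Random(seed)
    root = Node(children=[leaf(labels[0]), leaf(labels[1])])
    tree = RootedTree(root, validate=False)
    for label in labels[2:]:
        # pick a uniform random edge (= a uniform non-root node)
        nodes = [nd for nd in tree.preorder() if nd is not root]
        target = rng.choice(nodes)
        parent = target.parent
        idx = parent.children.index(target)
        joint = Node()
        joint.add_child(target)
        joint.add_child(leaf(label))
        joint.parent = parent
        parent.children[idx] = joint
    tree.validate()
    return tree


def matrix_from_tree(tree: RootedTree) -> CharacterMatrix:
    """Perfect binary matrix: one character per internal non-root clade,
    1 = member of the clade.  Inverse of the clade-reading step of the
    forest rewrite."""
    taxa = tuple(tree.leaf_labels())
    clades = [c for c in sorted(tree.clades(), key=lambda c: (-len(c),
                                                              sorted(c)))]
    cells = tuple(tuple("1" if t in c else "0" for c in clades)
                  for t in taxa)
    return CharacterMatrix(taxa, cells, alphabet="binary")


def perturb(matrix: CharacterMatrix, reversal_rate: float,
            seed: int) -> tuple[CharacterMatrix, list[tuple[str, int]]]:
    """Flip each 1-cell to 0 independently with probability
    ``reversal_rate``; returns the perturbed matrix and the flip log as
    ``(taxon, character-index)`` pairs."""
    if not 0 <= reversal_rate <= 1:
        raise HennigError("reversal rate must be a probability")
    rng = random.Random(seed)
    flips: list[tuple[str, int]] = []
    rows = []
    for taxon, row in zip(matrix.taxa, matrix.cells):
        new_row = list(row)
        for j, state in enumerate(row):
            if state == "1" and rng.random() < reversal_rate:
                new_row[j] = "0"
                flips.append((taxon, j))
        rows.append(tuple(new_row))
    out = CharacterMatrix(matrix.taxa, tuple(rows), matrix.alphabet,
                          matrix.outgroup, matrix.char_names)
    return out, flips


def homoplasy_free_dna(tree: RootedTree, sites_per_edge: int,
                       seed: int) -> CharacterMatrix:
    """DNA alignment in which every site changes exactly once on ``tree``.

    Each non-root edge receives ``sites_per_edge`` private sites; at such a
    site the clade below the edge carries one base and everyone else
    another, so the parsimony length of the alignment on the tree equals
    the number of substitutions and CI = RI = 1.
    """
    if sites_per_edge < 1:
        raise HennigError("sites_per_edge must be at least 1")
    rng = random.Random(seed)
    taxa = tree.leaf_labels()
    clades = []
    labels_below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            labels_below[id(node)] = frozenset([node.label])
        else:
            labels_below[id(node)] = frozenset().union(
                *(labels_below[id(c)] for c in node.children))
        if node is not tree.root:
            clades.append(labels_below[id(node)])
    columns = []
    for clade_members in clades:
        for _ in range(sites_per_edge):
            ancestral, derived = rng.sample("ACGT", 2)
            columns.append(tuple(derived if t in clade_members else ancestral
                                 for t in taxa))
    cells = tuple(tuple(col[i] for col in columns)
                  for i in range(len(taxa)))
    return CharacterMatrix(tuple(taxa), cells, alphabet="dna")
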