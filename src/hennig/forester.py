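"""Rewrite binary character matrices as forests of rooted character-state
trees ("Hennigian forests").

A binary character with state 1 declared apomorphic is a rooted tree whose
single clade is exactly the taxa scored 1.  Three rendering modes exist:

``with_poly``
    every character; uninformative characters become one complete polytomy
    over the scored taxa.
``no_poly``
    informative characters only, re-rooted against the outgroup:
    ``(outgroup, (rest..., (ones...)))``.
``additional``
    informative characters only, basal-polytomy form:
    ``(rest..., (ones...))``.

Missing entries are handled either by pruning the affected taxon from the
character's tree (``prune``) or by expanding the character into one tree per
completion of its ``?`` cells (``expand``).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Optional

from .model import (MISSING, CharacterMatrix, Forest, HennigError, MatrixError,
                    Node, RootedTree, leaf)

MODES = ("with_poly", "no_poly", "additional")
MISSING_POLICIES = ("prune", "expand")


class CharacterError(HennigError):
    """A character violates the preconditions of the requested rewrite."""


@dataclass
class ForestBundle:
    """The three output forests of a matrix rewrite."""

    with_poly: Forest
    no_poly: Forest
    additional: Forest


def _require_binary(matrix: CharacterMatrix) -> None:
    if matrix.alphabet != "binary":
        raise MatrixError(
            f"expected a binary matrix, got alphabet {matrix.alphabet!r}")


def is_informative(column: Iterable[str]) -> bool:
    """A column groups taxa only if >=2 ones and >=2 zeros are scored."""
    states = [s for s in column if s != MISSING]
    ones = sum(1 for s in states if s == "1")
    zeros = len(states) - ones
    return ones >= 2 and zeros >= 2

def _build_tree(taxa: list[str], states: list[str], mode: str,
                outgroup: Optional[str]) -> RootedTree:
    """Tree for a fully scored binary column over ``taxa``."""
    ones = [t for t, s in zip(taxa, states) if s == "1"]
    if not is_informative(states):
        # collapses to one complete polytomy regardless of mode
        if len(taxa) < 2:
            raise CharacterError("fewer than two scored taxa")
        return RootedTree(Node(children=[leaf(t) for t in taxa]))
    if mode == "no_poly":
        if outgroup is None:
            raise CharacterError("no_poly mode requires an outgroup")
        if outgroup in ones:
            raise CharacterError(
                f"outgroup {outgroup!r} carries the apomorphic state;"
                " character conflicts with the a priori polarity")
        rest = [t for t in taxa if t not in ones and t != outgroup]
        ingroup = Node(children=[leaf(t) for t in rest]
                       + [Node(children=[leaf(t) for t in ones])])
        return RootedTree(Node(children=[leaf(outgroup), ingroup]))
    # with_poly (informative case) and additional share the basal-polytomy form
    rest = [t for t in taxa if t not in ones]
    return RootedTree(Node(children=[leaf(t) for t in rest]
                           + [Node(children=[leaf(t) for t in ones])]))


def character_to_tree(matrix: CharacterMatrix, char_index: int,
                      mode: str = "additional",
                      missing_policy: str = "prune",
                      outgroup: Optional[str] = None) -> list[RootedTree]:
    """Rewrite one binary character as its rooted tree(s).

    Returns a list (deduplicated, input order) because the ``expand``
    policy yields one tree per completion of the missing cells.  An
    outgroup scored ``?`` is assumed plesiomorphic (state 0) and is never
    pruned nor expanded.
    """
    _require_binary(matrix)
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    column = list(matrix.column(char_index))
    taxa = list(matrix.taxa)
    if outgroup is None:
        outgroup = matrix.outgroup
    if outgroup is not None and outgroup not in taxa:
        raise MatrixError(f"outgroup {outgroup!r} is not a taxon")

    # outgroup '?' is assumed 0 up front
    if outgroup is not None:
        og_idx = taxa.index(outgroup)
        if column[og_idx] == MISSING:
            column[og_idx] = "0"
        if mode == "no_poly" and column[og_idx] == "1":
            raise CharacterError(
                f"character {char_index + 1}: outgroup {outgroup!r} is scored"
                " 1; conflicts with the a priori polarity")

    missing_at = [i for i, s in enumerate(column) if s == MISSING]
    if len(missing_at) == len(column):
        raise CharacterError(f"character {char_index + 1}: all taxa missing")

    completions: list[tuple[list[str], list[str]]] = []
    if missing_policy == "prune" or not missing_at:
        kept = [i for i in range(len(taxa)) if i not in missing_at]
        completions.append(([taxa[i] for i in kept],
                            [column[i] for i in kept]))
    else:
        for fill in product("01", repeat=len(missing_at)):
            states = list(column)
            for pos, value in zip(missing_at, fill):
                states[pos] = value
            completions.append((taxa, states))

    trees: list[RootedTree] = []
    seen = set()
    for sub_taxa, states in completions:
        tree = _build_tree(list(sub_taxa), list(states), mode, outgroup)
        key = tree.topology_key()
        if key not in seen:
            seen.add(key)
            trees.append(tree)
    return trees


def build_forests(matrix: CharacterMatrix, outgroup: Optional[str] = None,
                  missing_policy: str = "prune") -> ForestBundle:
    """Rewrite every character of a binary matrix into the three forests.

    Character order is preserved and recorded as provenance.  Characters
    that are uninformative (after missing-data handling) appear only in the
    ``with_poly`` forest, as complete polytomies.
    """
    _require_binary(matrix)
    if outgroup is None:
        outgroup = matrix.default_outgroup()
    if outgroup not in matrix.taxa:
        raise MatrixError(f"outgroup {outgroup!r} is not a taxon")

    bundle = ForestBundle(Forest(), Forest(), Forest())
    for j in range(matrix.nchar):
        with_poly = character_to_tree(matrix, j, "with_poly",
                                      missing_policy, outgroup)
        for tree in with_poly:
            bundle.with_poly.append(tree, provenance=j)
        informative = [t for t in with_poly if t.clades()]
        if not informative:
            continue
        for mode, forest in (("no_poly", bundle.no_poly),
                             ("additional", bundle.additional)):
            for tree in character_to_tree(matrix, j, mode,
                                          missing_policy, outgroup):
                if tree.clades():  # drop uninformative completions
                    forest.append(tree, provenance=j)
    return bundle


def minimal_trees_from_3ts(matrix: CharacterMatrix) -> Forest:
    """Rewrite a three-taxon-statement matrix as minimal trees.

    Every column must score exactly three taxa: one 0 (the outer taxon) and
    two 1s; the rest must be ``?``.  Column ``X=0, Y=1, Z=1`` becomes the
    minimal tree ``(X,(Y,Z))``.
    """
    _require_binary(matrix)
    forest = Forest()
    for j in range(matrix.nchar):
        column = matrix.column(j)
        scored = [(t, s) for t, s in zip(matrix.taxa, column) if s != MISSING]
        zeros = [t for t, s in scored if s == "0"]
        ones = [t for t, s in scored if s == "1"]
        if len(scored) != 3 or len(zeros) != 1 or len(ones) != 2:
            raise CharacterError(
                f"character {j + 1} is not a three-taxon statement"
                f" ({len(zeros)} zeros, {len(ones)} ones,"
                f" {len(scored)} scored)")
        tree = RootedTree(Node(children=[
            leaf(zeros[0]), Node(children=[leaf(t) for t in ones])]))
        forest.append(tree, provenance=j)
    return forest
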