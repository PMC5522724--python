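"""Core domain types: character matrices, rooted trees, forests, distance tables.

The pipeline treats a binary character as a rooted tree whose single clade is
the set of taxa carrying the derived state.  Everything downstream (forests,
averaged path-length tables, least-squares fits) is built on the small set of
types defined here.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

MISSING = "?"
GAP = "-"

#: symbols legal for each alphabet tag (missing symbol always allowed on top)
ALPHABETS = {
    "binary": set("01"),
    "multistate": set("0123456789"),
    "dna": set("ACGTUacgtuRYSWKMBDHVNryswkmbdhvn-"),
}

_NEWICK_FORBIDDEN = re.compile(r"[(),;:\s\[\]']")


class HennigError(Exception):
    """Base class for all contract violations raised by this package."""


class ParseError(HennigError):
    """Malformed input file (matrix or tree)."""


class MatrixError(HennigError):
    """Character-matrix contract violation."""


class TreeError(HennigError):
    """Tree contract violation."""


# ---------------------------------------------------------------------------
# Character matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CharacterMatrix:
    """A taxa x characters state table with an optional designated outgroup.

    Parameters
    ----------
    taxa:
        Ordered, unique, non-empty taxon labels.
    cells:
        One row of single-character state symbols per taxon.
    alphabet:
        One of ``binary``, ``multistate``, ``dna``.
    outgroup:
        Optional label of the all-plesiomorphic reference taxon.  By
        convention the last taxon of a matrix plays this role when no
        explicit choice is made (see :meth:`default_outgroup`).
    char_names:
        Optional per-character names (used by the recoders).
    """

    taxa: tuple[str, ...]
    cells: tuple[tuple[str, ...], ...]
    alphabet: str = "binary"
    outgroup: Optional[str] = None
    char_names: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.alphabet not in ALPHABETS:
            raise MatrixError(f"unknown alphabet {self.alphabet!r}")
        if len(self.taxa) != len(set(self.taxa)):
            raise MatrixError("taxon labels must be unique")
        if any(not t for t in self.taxa):
            raise MatrixError("taxon labels must be non-empty")
        if len(self.cells) != len(self.taxa):
            raise MatrixError(
                f"{len(self.taxa)} taxa but {len(self.cells)} state rows"
            )
        widths = {len(r) for r in self.cells}
        if len(widths) > 1:
            raise MatrixError(f"rows have unequal lengths: {sorted(widths)}")
        legal = ALPHABETS[self.alphabet] | {MISSING}
        for taxon, row in zip(self.taxa, self.cells):
            for j, state in enumerate(row):
                if state not in legal:
                    raise MatrixError(
                        f"illegal state {state!r} for taxon {taxon!r},"
                        f" character {j + 1} (alphabet {self.alphabet})"
                    )
        if self.outgroup is not None and self.outgroup not in self.taxa:
            raise MatrixError(f"outgroup {self.outgroup!r} is not a taxon")
        if self.char_names is not None and len(self.char_names) != self.nchar:
            raise MatrixError("char_names length must equal character count")

    # -- basic accessors ----------------------------------------------------

    @property
    def ntax(self) -> int:
        return len(self.taxa)

    @property
    def nchar(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def row(self, taxon: str) -> tuple[str, ...]:
        return self.cells[self.taxa.index(taxon)]

    def column(self, j: int) -> tuple[str, ...]:
        if not 0 <= j < self.nchar:
            raise MatrixError(f"character index {j} out of range")
        return tuple(row[j] for row in self.cells)

    def columns(self) -> Iterator[tuple[str, ...]]:
        for j in range(self.nchar):
            yield self.column(j)

    def default_outgroup(self) -> str:
        """Explicit outgroup if set, else the last taxon (file convention)."""
        return self.outgroup if self.outgroup is not None else self.taxa[-1]

    def with_outgroup(self, name: Optional[str]) -> "CharacterMatrix":
        return CharacterMatrix(self.taxa, self.cells, self.alphabet, name,
                               self.char_names)

    def take_characters(self, indices: Sequence[int]) -> "CharacterMatrix":
        cells = tuple(tuple(row[j] for j in indices) for row in self.cells)
        names = (tuple(self.char_names[j] for j in indices)
                 if self.char_names is not None else None)
        return CharacterMatrix(self.taxa, cells, self.alphabet,
                               self.outgroup, names)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str]],
                  alphabet: str = "binary",
                  outgroup: Optional[str] = None) -> "CharacterMatrix":
        """Build from ``(taxon, state-string)`` pairs."""
        taxa, cells = [], []
        for taxon, states in rows:
            taxa.append(taxon)
            cells.append(tuple(states))
        return cls(tuple(taxa), tuple(cells), alphabet, outgroup)


# ---------------------------------------------------------------------------
# Rooted trees
# ---------------------------------------------------------------------------


class Node:
    """A tree node; leaves carry a taxon ``label``, edges a ``length``.

    ``length`` is the length of the edge to the parent (ignored on roots);
    it defaults to unity, the convention used throughout the pipeline.
    """

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: float = 1.0,
                 children: Optional[list["Node"]] = None):
        self.label = label
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        for child in children or []:
            self.add_child(child)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r})" if self.is_leaf else (
            f"Node(<{len(self.children)} children>)")


def leaf(label: str, length: float = 1.0) -> Node:
    return Node(label=label, length=length)


def clade(*children: Node, length: float = 1.0) -> Node:
    return Node(length=length, children=list(children))


class RootedTree:
    """A rooted, polytomy-permitting tree over uniquely labelled leaves.

    ``rooted=False`` marks trees whose root placement is arbitrary (results
    of unrooted estimation); the structure is identical either way.
    """

    def __init__(self, root: Node, rooted: bool = True, validate: bool = True):
        self.root = root
        self.rooted = rooted
        if validate:
            self.validate()

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_label_groups(cls, *groups, rooted: bool = True) -> "RootedTree":
        """Build from nested label structures, e.g. ``("A", ("B", "C"))``.

        Strings become leaves, tuples/lists become internal nodes; all edge
        lengths are unity.
        """

        def build(item) -> Node:
            if isinstance(item, str):
                return leaf(item)
            return Node(children=[build(x) for x in item])

        if len(groups) == 1 and not isinstance(groups[0], str):
            groups = tuple(groups[0])
        return cls(Node(children=[build(g) for g in groups]), rooted=rooted)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate leaf labels")
        for node in self.preorder():
            if not node.is_leaf and len(node.children) < 2:
                raise TreeError("internal node with fewer than 2 children")
            if node is not self.root and node.length < 0:
                raise TreeError("negative stored edge length")
            if node.is_leaf and not node.label:
                raise TreeError("unlabelled leaf")

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def clades(self, include_root: bool = False) -> set[frozenset[str]]:
        """Leaf-label sets of internal nodes (root excluded by default)."""
        out: set[frozenset[str]] = set()
        labels_below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                labels_below[id(node)] = frozenset([node.label])
            else:
                merged = frozenset().union(
                    *(labels_below[id(c)] for c in node.children))
                labels_below[id(node)] = merged
                if include_root or node is not self.root:
                    out.add(merged)
        return out

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartition halves, canonicalised to exclude the
        lexicographically smallest leaf (root-position independent)."""
        all_leaves = frozenset(self.leaf_labels())
        anchor = min(all_leaves)
        out = set()
        for cl in self.clades(include_root=False):
            side = all_leaves - cl if anchor in cl else cl
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return out

    def topology_key(self) -> frozenset:
        """Hashable identity: leaf set + clade sets (rooted comparison)."""
        return frozenset([frozenset(self.leaf_labels()),
                          frozenset(self.clades())])

    # -- editing ------------------------------------------------------------

    def copy(self) -> "RootedTree":
        def dup(node: Node) -> Node:
            new = Node(label=node.label, length=node.length)
            for child in node.children:
                new.add_child(dup(child))
            return new

        return RootedTree(dup(self.root), rooted=self.rooted, validate=False)

    def is_binary(self) -> bool:
        """True if every internal node is bifurcating (root may be
        trifurcating when the tree is unrooted)."""
        for node in self.preorder():
            if node.is_leaf:
                continue
            limit = 3 if (node is self.root and not self.rooted) else 2
            if len(node.children) > limit:
                return False
        return True

    # -- serialisation ------------------------------------------------------

    def newick(self, lengths: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                if _NEWICK_FORBIDDEN.search(node.label or ""):
                    raise TreeError(
                        f"label {node.label!r} contains Newick metacharacters"
                    )
                core = node.label
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if lengths and node.parent is not None:
                core += f":{node.length:g}"
            return core

        if self.root.is_leaf:
            raise TreeError("single-leaf tree has no informative structure")
        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RootedTree({self.newick()})"


# ---------------------------------------------------------------------------
# Forest
# ---------------------------------------------------------------------------


@dataclass
class Forest:
    """An ordered, equally weighted collection of rooted trees.

    ``provenance`` records, per tree, the 0-based index of the source
    character (or ``None`` for trees not derived from a matrix).
    """

    trees: list[RootedTree] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)
    provenance: list[Optional[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.weights:
            self.weights = [1.0] * len(self.trees)
        if not self.provenance:
            self.provenance = [None] * len(self.trees)
        if len(self.weights) != len(self.trees):
            raise HennigError("weights length must equal tree count")
        if len(self.provenance) != len(self.trees):
            raise HennigError("provenance length must equal tree count")
        if any(w <= 0 for w in self.weights):
            raise HennigError("tree weights must be positive")

    def append(self, tree: RootedTree, provenance: Optional[int] = None,
               weight: float = 1.0) -> None:
        self.trees.append(tree)
        self.weights.append(weight)
        self.provenance.append(provenance)

    def extend(self, other: "Forest") -> None:
        for tree, w, p in zip(other.trees, other.weights, other.provenance):
            self.append(tree, p, w)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[RootedTree]:
        return iter(self.trees)

    def taxa(self) -> list[str]:
        """Union of leaf labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for tree in self.trees:
            for label in tree.leaf_labels():
                seen.setdefault(label)
        return list(seen)


# ---------------------------------------------------------------------------
# Distance table
# ---------------------------------------------------------------------------


class DistanceTable:
    """Symmetric table of averaged path lengths with per-pair coverage."""

    def __init__(self, taxa: Sequence[str], d: np.ndarray,
                 coverage: Optional[np.ndarray] = None):
        taxa = tuple(taxa)
        d = np.asarray(d, dtype=float)
        n = len(taxa)
        if d.shape != (n, n):
            raise HennigError(f"distance matrix shape {d.shape} != ({n},{n})")
        if len(set(taxa)) != n:
            raise HennigError("duplicate taxa in distance table")
        if not np.allclose(d, d.T, atol=1e-12):
            raise HennigError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise HennigError("distance matrix diagonal is not zero")
        if coverage is None:
            coverage = np.ones((n, n), dtype=int)
            np.fill_diagonal(coverage, 0)
        coverage = np.asarray(coverage, dtype=int)
        for i in range(n):
            for j in range(i + 1, n):
                if coverage[i, j] < 1:
                    raise HennigError(
                        f"pair ({taxa[i]!r}, {taxa[j]!r}) has no coverage")
        self.taxa = taxa
        self.d = d
        self.coverage = coverage

    @property
    def ntax(self) -> int:
        return len(self.taxa)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])

    def reorder(self, taxa: Sequence[str]) -> "DistanceTable":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceTable(taxa, self.d[np.ix_(idx, idx)],
                             self.coverage[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """A topology with fitted branch lengths and its criterion score."""

    tree: RootedTree
    score: float
    criterion: str
    taxa: tuple[str, ...]
    p: np.ndarray  # implied patristic distances, aligned with `taxa`
    config: Optional[object] = None

    def __post_init__(self) -> None:
        if self.criterion in ("ols", "wls") and self.score < -1e-9:
            raise HennigError("least-squares score cannot be negative")
        self.score = float(self.score)

    def implied_distance(self, a: str, b: str) -> float:
        return float(self.p[self.taxa.index(a), self.taxa.index(b)])


def patristic_matrix(tree: RootedTree, taxa: Sequence[str],
                     use_lengths: bool = True) -> np.ndarray:
    """Pairwise path-length matrix of ``tree`` aligned with ``taxa``.

    The tree is regarded as an unrooted graph: the root contributes no
    special edges, so a degree-2 root simply lies on the path through it.
    """
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    out = np.zeros((n, n))
    masks: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in index:
                raise TreeError(f"leaf {node.label!r} not in taxa")
            masks[id(node)] = 1 << index[node.label]
        else:
            m = 0
            for child in node.children:
                m |= masks[id(child)]
            masks[id(node)] = m
    for node in tree.preorder():
        if node is tree.root:
            continue
        m = masks[id(node)]
        w = node.length if use_lengths else 1.0
        below = [i for i in range(n) if (m >> i) & 1]
        above = [i for i in range(n) if not (m >> i) & 1]
        for i in below:
            for j in above:
                out[i, j] += w
                out[j, i] += w
    return out
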