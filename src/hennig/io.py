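"""Readers and writers: relaxed non-interleaved PHYLIP matrices and
one-tree-per-line Newick files.

The matrix dialect accepts both whitespace-separated states and a single
contiguous state string; taxon labels may not contain whitespace.  The
Newick dialect is deliberately plain: unquoted labels, one semicolon-
terminated tree per line, branch lengths optional on input and omitted on
output (unit lengths are implicit).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, TextIO, Union

import dendropy

from .model import (MISSING, CharacterMatrix, Forest, Node, ParseError,
                    RootedTree, TreeError)

PathLike = Union[str, Path]


def _open_text(source: Union[PathLike, TextIO], mode: str = "r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode, encoding="utf-8", newline=""), True


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def read_matrix(source: Union[PathLike, TextIO], alphabet: str = "binary",
                outgroup: Optional[str] = None) -> CharacterMatrix:
    """Read a relaxed, non-interleaved PHYLIP matrix.

    The header line gives ``ntax nchar``; each following non-blank line is a
    whitespace-free taxon label followed by its states, either as single
    whitespace-separated symbols or as one contiguous string.
    """
    handle, close = _open_text(source)
    try:
        lines = handle.read().splitlines()
    finally:
        if close:
            handle.close()

    body = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not body:
        raise ParseError("empty matrix file")
    lineno, header = body[0]
    parts = header.split()
    if len(parts) != 2:
        raise ParseError(f"line {lineno}: header must be 'ntax nchar'")
    try:
        ntax, nchar = int(parts[0]), int(parts[1])
    except ValueError:
        raise ParseError(f"line {lineno}: header must be two integers") from None
    if ntax < 0 or nchar < 0:
        raise ParseError(f"line {lineno}: negative dimensions")

    rows: list[tuple[str, tuple[str, ...]]] = []
    for lineno, line in body[1:]:
        tokens = line.split()
        label = tokens[0]
        states = "".join(tokens[1:])
        if len(states) != nchar:
            raise ParseError(
                f"line {lineno}: taxon {label!r} has {len(states)} states,"
                f" expected {nchar}")
        rows.append((label, tuple(states)))
    if len(rows) != ntax:
        raise ParseError(
            f"header declares {ntax} taxa but {len(rows)} data lines found")
    taxa = tuple(label for label, _ in rows)
    cells = tuple(states for _, states in rows)
    return CharacterMatrix(taxa, cells, alphabet=alphabet, outgroup=outgroup)


def write_matrix(matrix: CharacterMatrix,
                 target: Union[PathLike, TextIO]) -> None:
    """Write a matrix in the same relaxed PHYLIP dialect (contiguous states)."""
    handle, close = _open_text(target, "w")
    try:
        handle.write(f"{matrix.ntax} {matrix.nchar}\n")
        width = max((len(t) for t in matrix.taxa), default=0)
        for taxon, row in zip(matrix.taxa, matrix.cells):
            handle.write(f"{taxon:<{width}}  {''.join(row)}\n")
    finally:
        if close:
            handle.close()


def matrix_to_string(matrix: CharacterMatrix) -> str:
    buf = _io.StringIO()
    write_matrix(matrix, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: "dendropy.Tree") -> RootedTree:
    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            if not label:
                raise ParseError("leaf without a label")
            node = Node(label=label)
        else:
            node = Node(children=[convert(c) for c in dnode.child_nodes()])
        node.length = 1.0 if dnode.edge.length is None else float(
            dnode.edge.length)
        return node

    return RootedTree(convert(dtree.seed_node))


def parse_newick(text: str) -> RootedTree:
    """Parse a single rooted Newick string; absent lengths default to unity."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True)
    except Exception as exc:
        raise ParseError(f"invalid Newick: {exc}") from None
    return _from_dendropy(dtree)


def read_newick(source: Union[PathLike, TextIO]) -> Forest:
    """Read a one-tree-per-line Newick file into a Forest (unit weights)."""
    handle, close = _open_text(source)
    try:
        lines = handle.read().splitlines()
    finally:
        if close:
            handle.close()
    forest = Forest()
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        try:
            tree = parse_newick(line)
        except ParseError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        forest.append(tree)
    return forest


def write_newick(trees: Union[Forest, RootedTree],
                 target: Union[PathLike, TextIO],
                 lengths: bool = False) -> None:
    """Write one semicolon-terminated tree per line, unquoted labels.

    Labels containing Newick metacharacters are rejected rather than quoted;
    branch lengths are omitted unless ``lengths`` is set (unity is implicit).
    """
    if isinstance(trees, RootedTree):
        tree_list = [trees]
    else:
        tree_list = list(trees)
    if not tree_list:
        raise TreeError("refusing to write an empty tree file")
    handle, close = _open_text(target, "w")
    try:
        for tree in tree_list:
            handle.write(tree.newick(lengths=lengths) + "\n")
    finally:
        if close:
            handle.close()
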