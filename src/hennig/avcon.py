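"""Average-consensus distance tables: per-tree path-length matrices at unit
branch lengths, averaged with equal tree weights.

For each unordered taxon pair the table entry is the arithmetic mean of the
path lengths over the trees in which both taxa occur; per-pair coverage
counts are kept alongside.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import TextIO, Union

import numpy as np

from .model import (DistanceTable, Forest, HennigError, ParseError,
                    RootedTree, TreeError, patristic_matrix)

PathLike = Union[str, Path]


def path_length_matrix(tree: RootedTree,
                       use_lengths: bool = False) -> dict[frozenset, float]:
    """Pairwise path lengths of one tree, as a mapping on label pairs.

    The tree is regarded as an unrooted graph (the root is an ordinary
    vertex of its degree).  With ``use_lengths`` off every edge counts one.
    """
    if tree.n_leaves < 2:
        raise TreeError("need at least two leaves")
    taxa = tree.leaf_labels()
    if len(taxa) != len(set(taxa)):
        raise TreeError("duplicate leaf labels")
    mat = patristic_matrix(tree, taxa, use_lengths=use_lengths)
    out: dict[frozenset, float] = {}
    for i, a in enumerate(taxa):
        for j in range(i + 1, len(taxa)):
            out[frozenset((a, taxa[j]))] = float(mat[i, j])
    return out


def average_consensus_table(forest: Forest,
                            use_lengths: bool = False) -> DistanceTable:
    """Average the per-tree path-length matrices of an equally weighted
    forest.

    Branch lengths are forced to unity unless ``use_lengths`` is set.  Pairs
    are averaged over the trees in which they co-occur; a pair that never
    co-occurs is an error.
    """
    if len(forest) == 0:
        raise HennigError("empty forest")
    if len(set(forest.weights)) > 1:
        raise HennigError("average consensus requires equal tree weights")
    taxa = forest.taxa()
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    for tree in forest:
        labels = tree.leaf_labels()
        mat = patristic_matrix(tree, labels, use_lengths=use_lengths)
        idx = [index[t] for t in labels]
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                i, j = idx[a], idx[b]
                total[i, j] += mat[a, b]
                total[j, i] += mat[a, b]
                count[i, j] += 1
                count[j, i] += 1
    for i in range(n):
        for j in range(i + 1, n):
            if count[i, j] == 0:
                raise HennigError(
                    f"taxa {taxa[i]!r} and {taxa[j]!r} never co-occur"
                    " in any tree")
    d = np.divide(total, count, out=np.zeros_like(total),
                  where=count > 0)
    return DistanceTable(taxa, d, count)


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def _open_text(source, mode="r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode, encoding="utf-8", newline=""), True


def write_distance_table(table: DistanceTable,
                         target: Union[PathLike, TextIO],
                         format: str = "phylip-square") -> None:
    """Write a full symmetric square matrix (>=10 significant digits)."""
    if table.ntax == 0:
        raise HennigError("empty distance table")
    handle, close = _open_text(target, "w")
    try:
        if format == "phylip-square":
            handle.write(f"{table.ntax}\n")
            width = max(len(t) for t in table.taxa)
            for i, taxon in enumerate(table.taxa):
                row = " ".join(f"{x:.10g}" for x in table.d[i])
                handle.write(f"{taxon:<{width}}  {row}\n")
        elif format == "nexus-distances":
            handle.write("#NEXUS\n")
            handle.write("BEGIN TAXA;\n")
            handle.write(f"  DIMENSIONS NTAX={table.ntax};\n")
            handle.write("  TAXLABELS " + " ".join(table.taxa) + ";\n")
            handle.write("END;\n")
            handle.write("BEGIN DISTANCES;\n")
            handle.write("  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\n")
            handle.write("  MATRIX\n")
            for i, taxon in enumerate(table.taxa):
                row = " ".join(f"{x:.10g}" for x in table.d[i])
                handle.write(f"    {taxon} {row}\n")
            handle.write("  ;\nEND;\n")
        else:
            raise ValueError(f"unknown format {format!r}")
    finally:
        if close:
            handle.close()


def read_distance_table(source: Union[PathLike, TextIO]) -> DistanceTable:
    """Read a distance table written by :func:`write_distance_table`
    (either format)."""
    handle, close = _open_text(source)
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    if text.lstrip().upper().startswith("#NEXUS"):
        match = re.search(r"MATRIX(.*?);", text, re.S | re.I)
        if not match:
            raise ParseError("no MATRIX block found")
        rows = [ln.split() for ln in match.group(1).splitlines()
                if ln.strip()]
    else:
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise ParseError("empty distance file")
        try:
            ntax = int(lines[0].split()[0])
        except ValueError:
            raise ParseError("phylip distance file must start with ntax")
        rows = [ln.split() for ln in lines[1:]]
        if len(rows) != ntax:
            raise ParseError(f"expected {ntax} rows, found {len(rows)}")
    taxa = [r[0] for r in rows]
    try:
        d = np.array([[float(x) for x in r[1:]] for r in rows])
    except ValueError as exc:
        raise ParseError(f"bad distance value: {exc}") from None
    return DistanceTable(taxa, d)
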