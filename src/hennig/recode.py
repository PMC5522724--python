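"""Recoders that produce binary matrices: per-base presence/absence coding
of DNA alignments, additive binary coding of ordered multistate characters,
and the artificial all-zero outgroup row.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .model import GAP, MISSING, CharacterMatrix, MatrixError

_UNAMBIGUOUS = set("ACGT")


def _normalise_base(symbol: str) -> str:
    """Uppercase, U->T; anything outside {A,C,G,T} is treated as missing."""
    s = symbol.upper()
    if s == "U":
        s = "T"
    return s if s in _UNAMBIGUOUS else MISSING


def dna_presence_absence(alignment: CharacterMatrix,
                         outgroup: Optional[str] = None) -> CharacterMatrix:
    """Recode a DNA alignment as binary presence/absence characters.

    For each alignment column and each unambiguous base observed in it, a
    binary character is emitted: 1 = taxon carries that base, 0 = taxon
    carries a different unambiguous base, '?' = gap or ambiguity.  Character
    names follow the ``s{site}={base}`` convention (1-based sites).

    When ``outgroup`` is given, columns where the outgroup is ambiguous are
    discarded before recoding, and only characters with outgroup state 0 are
    kept (the outgroup is declared all-plesiomorphic).  With no outgroup the
    full recoding is returned.
    """
    if alignment.alphabet != "dna":
        raise MatrixError("dna_presence_absence requires a DNA alignment")
    if outgroup is not None and outgroup not in alignment.taxa:
        raise MatrixError(f"outgroup {outgroup!r} is not a taxon")
    og_idx = alignment.taxa.index(outgroup) if outgroup is not None else None

    columns: list[tuple[str, ...]] = []
    names: list[str] = []
    for site in range(alignment.nchar):
        bases = [_normalise_base(s) for s in alignment.column(site)]
        if og_idx is not None and bases[og_idx] == MISSING:
            continue  # ambiguous outgroup: column discarded up front
        observed = sorted({b for b in bases if b != MISSING})
        for base in observed:
            states = tuple(MISSING if b == MISSING else
                           ("1" if b == base else "0") for b in bases)
            if og_idx is not None and states[og_idx] != "0":
                continue  # keep only outgroup-zero characters
            columns.append(states)
            names.append(f"s{site + 1}={base}")

    cells = tuple(tuple(col[i] for col in columns)
                  for i in range(alignment.ntax))
    return CharacterMatrix(alignment.taxa, cells, alphabet="binary",
                           outgroup=outgroup, char_names=tuple(names))


def additive_binary(matrix: CharacterMatrix,
                    ordered_chars: Iterable[int] = ()) -> CharacterMatrix:
    """Additively recode ordered multistate characters into binary columns.

    An ordered character with maximum observed state ``m`` becomes ``m``
    binary columns; state ``k`` maps to ``k`` ones followed by ``m - k``
    zeros, and ``?`` maps to ``?`` throughout.  Characters not listed in
    ``ordered_chars`` (0-based indices) must already be binary and pass
    through unchanged.
    """
    ordered = set(ordered_chars)
    for j in ordered:
        if not 0 <= j < matrix.nchar:
            raise MatrixError(f"ordered character index {j} out of range")

    columns: list[tuple[str, ...]] = []
    names: list[str] = []

    def name_of(j: int) -> str:
        if matrix.char_names is not None:
            return matrix.char_names[j]
        return f"c{j + 1}"

    for j in range(matrix.nchar):
        column = matrix.column(j)
        if j not in ordered:
            bad = {s for s in column} - {"0", "1", MISSING}
            if bad:
                raise MatrixError(
                    f"character {j + 1} has non-binary states {sorted(bad)};"
                    " list it in ordered_chars to recode it")
            columns.append(column)
            names.append(name_of(j))
            continue
        observed = []
        for s in column:
            if s == MISSING:
                continue
            if not s.isdigit():
                raise MatrixError(
                    f"character {j + 1}: non-integer state {s!r}")
            observed.append(int(s))
        m = max(observed, default=0)
        for k in range(1, m + 1):  # threshold characters: state >= k
            states = tuple(MISSING if s == MISSING else
                           ("1" if int(s) >= k else "0") for s in column)
            columns.append(states)
            names.append(f"{name_of(j)}>={k}")

    cells = tuple(tuple(col[i] for col in columns)
                  for i in range(matrix.ntax))
    return CharacterMatrix(matrix.taxa, cells, alphabet="binary",
                           outgroup=matrix.outgroup, char_names=tuple(names))


def add_allzero_outgroup(matrix: CharacterMatrix,
                         name: str = "ROOT") -> CharacterMatrix:
    """Append an artificial all-zero taxon as the last row and make it the
    outgroup."""
    if matrix.alphabet != "binary":
        raise MatrixError("all-zero outgroup applies to binary matrices")
    if name in matrix.taxa:
        raise MatrixError(f"taxon {name!r} already exists")
    taxa = matrix.taxa + (name,)
    cells = matrix.cells + (("0",) * matrix.nchar,)
    return CharacterMatrix(taxa, cells, alphabet="binary", outgroup=name,
                           char_names=matrix.char_names)
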