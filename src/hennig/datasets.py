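"""Built-in fixtures and loaders for published worked examples.

The one matrix small enough to be carried in code is the classic
five-taxon example of three pairwise-conflicting characters; the other
worked examples circulated in the cladistics literature (Nelson &
Platnick's matrix 17, Kluge's tables 2 and 3, Harvey's figure-5 matrix,
Farris's matrix Z, and the eight-taxon hypothetical DNA alignment) are
loaded from plain-text files when a copy has been placed under
``data/worked/`` at the repository root (see :data:`WORKED_EXAMPLES`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .io import read_matrix
from .model import CharacterMatrix

#: directory searched for worked-example matrices (repository-root relative
#: fallback; an absolute path can be supplied to the loader instead)
DATA_DIR = Path(__file__).resolve().parents[2] / "data" / "worked"


def conflict_matrix() -> CharacterMatrix:
    """Five taxa, three pairwise-conflicting binary characters.

    Characters group (B,C), (B,D) and (C,D); O and A are all-plesiomorphic
    and O is the outgroup.  No single character supports the group (B,C,D),
    yet the averaged forest of the three character trees fits a tree
    containing it exactly.
    """
    return CharacterMatrix.from_rows(
        [("O", "000"),
         ("A", "000"),
         ("B", "110"),
         ("C", "101"),
         ("D", "011")],
        alphabet="binary", outgroup="O")


@dataclass(frozen=True)
class WorkedExample:
    """Registry entry for an externally published worked matrix."""

    name: str
    filename: str
    alphabet: str
    outgroup: str
    note: str


WORKED_EXAMPLES: dict[str, WorkedExample] = {
    "matrix17": WorkedExample(
        "matrix17", "matrix17.phy", "binary", "O",
        "Nelson & Platnick's matrix 17 (character four removed); "
        "7-ish taxa, 4 binary characters"),
    "kluge_table2": WorkedExample(
        "kluge_table2", "kluge_table2.phy", "binary", "X",
        "Kluge's table 2; 9 binary characters"),
    "kluge_table3": WorkedExample(
        "kluge_table3", "kluge_table3.phy", "binary", "X",
        "Kluge's table 3; 6 binary characters"),
    "harvey_fig5": WorkedExample(
        "harvey_fig5", "harvey_fig5.phy", "binary", "O",
        "Harvey's figure-5 matrix; 23 binary characters"),
    "matrix_z": WorkedExample(
        "matrix_z", "matrix_z.phy", "binary", "O",
        "Farris's matrix Z (Kluge's table 3 with every column doubled)"),
    "hypothetical_dna": WorkedExample(
        "hypothetical_dna", "hypothetical_dna.phy", "dna", "O",
        "Eight-ish taxon hypothetical non-clock DNA matrix"),
}


def worked_example_path(name: str,
                        data_dir: Optional[Path] = None) -> Path:
    try:
        entry = WORKED_EXAMPLES[name]
    except KeyError:
        raise KeyError(f"unknown worked example {name!r}; known:"
                       f" {sorted(WORKED_EXAMPLES)}") from None
    return (Path(data_dir) if data_dir is not None else DATA_DIR) \
        / entry.filename


def load_worked_example(name: str,
                        data_dir: Optional[Path] = None) -> CharacterMatrix:
    """Load a registered worked-example matrix from ``data/worked``.

    Raises FileNotFoundError with placement instructions when the file has
    not been supplied (these matrices are published in journal archives and
    are not redistributed here).
    """
    entry = WORKED_EXAMPLES[name]
    path = worked_example_path(name, data_dir)
    if not path.exists():
        raise FileNotFoundError(
            f"worked example {name!r} ({entry.note}) not found: place a"
            f" relaxed PHYLIP copy at {path}")
    return read_matrix(path, alphabet=entry.alphabet,
                       outgroup=entry.outgroup)
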