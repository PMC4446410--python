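"""The 85 canonical heavy-atom types of the four ribonucleotides.

Every heavy atom of A, U, C and G is its own type: the 12 sugar-phosphate
atoms shared by all residues plus the base atoms specific to each ring
system (purines A/G carry 10/11 base atoms, pyrimidines U/C carry 8 each),
85 in total.  Types are numbered 1..85 in block order A, U, C, G, with the
backbone row before the base row inside each block.  The numbering
convention is versioned (see ``CONVENTION``) and written into parameter
files so that trained tables are never mixed across conventions.
"""

from __future__ import annotations

from .errors import UnknownAtomTypeError

#: Identifier of the numbering convention, stored in parameter files.
CONVENTION = "block-AUCG-backbone-first-v1"

RESIDUE_CODES = ("A", "U", "C", "G")

#: Sugar-phosphate atoms common to every residue (non-base atoms).
BACKBONE_ATOMS = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'",
    "C3'", "O3'", "C2'", "O2'", "C1'",
)

#: Base (ring + exocyclic) atoms per residue code.
BASE_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
}

N_ATOM_TYPES = 85
#: Number of unordered atom-type pairs (85 choose 2 plus diagonal).
N_PAIR_TYPES = N_ATOM_TYPES * (N_ATOM_TYPES + 1) // 2


def _build_index() -> dict[tuple[str, str], int]:
    table: dict[tuple[str, str], int] = {}
    idx = 1
    for code in RESIDUE_CODES:
        for name in BACKBONE_ATOMS + BASE_ATOMS[code]:
            table[(code, name)] = idx
            idx += 1
    return table


#: mapping (residue code, atom name) -> 1-based atom-type index
ATOM_TYPE_INDEX: dict[tuple[str, str], int] = _build_index()

assert len(ATOM_TYPE_INDEX) == N_ATOM_TYPES


def atom_type_index(code: str, name: str) -> int:
    """Return the 1-based type index of atom *name* in residue *code*.

    Raises
    ------
    UnknownAtomTypeError
        If the (code, name) pair is not one of the 85 canonical types.
    """
    try:
        return ATOM_TYPE_INDEX[(code, name)]
    except KeyError:
        raise UnknownAtomTypeError(f"unknown atom type ({code!r}, {name!r})") from None


def is_base_atom(code: str, name: str) -> bool:
    """True if the typed atom belongs to the base, False for sugar/phosphate."""
    if (code, name) not in ATOM_TYPE_INDEX:
        raise UnknownAtomTypeError(f"unknown atom type ({code!r}, {name!r})")
    return name not in BACKBONE_ATOMS


def pair_row(a: int, b: int) -> int:
    """0-based row index of the unordered type pair (*a*, *b*), 1-based inputs.

    Rows enumerate pairs (i, j) with i <= j in lexicographic order; querying
    (a, b) and (b, a) therefore lands on the same row.
    """
    i, j = (a - 1, b - 1) if a <= b else (b - 1, a - 1)
    return i * N_ATOM_TYPES - i * (i + 1) // 2 + j
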