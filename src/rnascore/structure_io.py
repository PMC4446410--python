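"""PDB reading/writing and the validated in-memory RNA structure model.

Parsing is delegated to Bio.PDB; this module adds the policies a scoring
pipeline needs on top of a raw parse: atom-name dialect normalization
(``O5*``/``O1P`` vs ``O5'``/``OP1``), hydrogen removal, altloc resolution by
highest occupancy, restriction to the four standard ribonucleotides, and
chain-break flagging from the O3'(i)-P(i+1) distance.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

from .atom_types import ATOM_TYPE_INDEX, RESIDUE_CODES
from .errors import EmptyStructureError, MissingModelError

log = logging.getLogger(__name__)

#: O3'-P distance above which backbone connectivity is considered broken (Å).
CHAIN_BREAK_DISTANCE = 2.5


def normalize_atom_name(name: str) -> str:
    """Map PDB v2/v3 atom-name dialects onto one canonical spelling.

    ``*`` and the unicode prime are rewritten to ``'``; the old phosphate
    oxygen names ``O1P``/``O2P`` become ``OP1``/``OP2``.
    """
    name = name.strip().replace("*", "'").replace("′", "'")
    if name == "O1P":
        return "OP1"
    if name == "O2P":
        return "OP2"
    return name


@dataclass
class Atom:
    """One heavy atom: normalized name, Å coordinates, occupancy, altloc tag."""

    name: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r} has invalid coordinates")
        if not self.name:
            raise ValueError("atom name empty after normalization")


@dataclass
class Residue:
    """A standard ribonucleotide: code in {A,U,C,G}, chain position, atoms by name."""

    code: str
    seq_index: int
    atoms: dict[str, Atom] = field(default_factory=dict)
    label: str = ""  # author residue number + insertion code, for reporting

    def get(self, name: str) -> Atom | None:
        return self.atoms.get(name)

    def coord(self, name: str) -> np.ndarray | None:
        atom = self.atoms.get(name)
        return None if atom is None else atom.coords


@dataclass
class Chain:
    """An ordered run of residues plus the set of flagged backbone breaks."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    #: indices i such that the O3'(i)-P(i+1) linkage is broken or unverifiable
    breaks: set[int] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.residues)

    def is_linked(self, i: int) -> bool:
        """True if residues i and i+1 are backbone-bonded (no flagged break)."""
        return 0 <= i < len(self.residues) - 1 and i not in self.breaks


@dataclass
class Structure:
    """Chains of residues from one model of one PDB entry."""

    chains: list[Chain] = field(default_factory=list)
    source_id: str = ""
    model_index: int = 1

    def __iter__(self):
        return iter(self.chains)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def residues(self):
        """Yield (chain, residue) over all residues in file order."""
        for chain in self.chains:
            for res in chain.residues:
                yield chain, res


def flag_chain_breaks(structure: Structure) -> None:
    """Flag i -> i+1 backbone breaks wherever O3'-P exceeds the bond ceiling.

    A missing O3' or P also flags a break: connectivity cannot be certified,
    and torsions spanning the junction must stay undefined.
    """
    for chain in structure.chains:
        chain.breaks.clear()
        for i in range(len(chain.residues) - 1):
            o3 = chain.residues[i].coord("O3'")
            p = chain.residues[i + 1].coord("P")
            if o3 is None or p is None or math.dist(o3, p) > CHAIN_BREAK_DISTANCE:
                chain.breaks.add(i)


_RESNAME_ALIASES = {"A": "A", "U": "U", "C": "C", "G": "G",
                    "RA": "A", "RU": "U", "RC": "C", "RG": "G",
                    "ADE": "A", "URA": "U", "URI": "U", "CYT": "C", "GUA": "G"}


def _is_hydrogen(name: str, element: str) -> bool:
    if element.strip().upper() in ("H", "D"):
        return True
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() in ("H", "D")


def parse_pdb(source, model_index: int = 1, source_id: str = "") -> Structure:
    """Parse one model of a PDB file into a validated :class:`Structure`.

    Parameters
    ----------
    source
        File path, or a file-like / string containing PDB text.
    model_index
        1-based model to extract (NMR multi-model files); default first model.

    Hydrogens are dropped; altlocs resolve to the highest-occupancy copy
    (ties broken by file order); residues that are not standard A/U/C/G are
    skipped with a warning, as are heavy atoms not in the canonical type
    table; chain breaks are flagged afterwards.
    """
    if model_index < 1:
        raise ValueError("model_index must be >= 1")
    if hasattr(source, "read"):
        handle = source
    elif isinstance(source, str) and "\n" in source:
        handle = io.StringIO(source)
    else:
        handle = open(source)
        source_id = source_id or str(source)

    parser = PDBParser(QUIET=True)
    bio_structure = parser.get_structure(source_id or "rna", handle)
    models = list(bio_structure)
    if not models:
        raise EmptyStructureError("no models found in PDB input")
    if model_index > len(models):
        raise MissingModelError(
            f"model {model_index} requested but file has {len(models)} model(s)")
    bio_model = models[model_index - 1]

    structure = Structure(source_id=source_id, model_index=model_index)
    skipped_residues = 0
    for bio_chain in bio_model:
        chain = Chain(chain_id=bio_chain.id.strip() or "A")
        for bio_res in bio_chain:
            resname = bio_res.get_resname().strip()
            code = _RESNAME_ALIASES.get(resname)
            if code is None:
                skipped_residues += 1
                log.warning("skipping non-standard residue %r %s in chain %s",
                            resname, bio_res.id[1], bio_chain.id)
                continue
            hetflag, resseq, icode = bio_res.id
            residue = Residue(code=code, seq_index=len(chain.residues) + 1,
                              label=f"{resseq}{icode.strip()}")
            # altloc resolution: group file-order copies by normalized name,
            # keep the highest occupancy (ties -> first seen).
            best: dict[str, Atom] = {}
            for bio_atom in bio_res.get_unpacked_list():
                name = normalize_atom_name(bio_atom.get_name())
                if _is_hydrogen(name, bio_atom.element or ""):
                    continue
                if (code, name) not in ATOM_TYPE_INDEX:
                    log.warning("skipping atom %r not in the canonical type "
                                "table for residue %s", name, code)
                    continue
                occ = bio_atom.get_occupancy()
                occ = 1.0 if occ is None else float(occ)
                atom = Atom(name=name, coords=np.array(bio_atom.get_coord(), dtype=float),
                            occupancy=occ, altloc=(bio_atom.get_altloc() or "").strip())
                if name not in best or occ > best[name].occupancy:
                    best[name] = atom
            if best:
                residue.atoms = best
                chain.residues.append(residue)
        if chain.residues:
            structure.chains.append(chain)

    if structure.n_atoms == 0:
        raise EmptyStructureError("no parseable nucleotide atoms in PDB input")
    flag_chain_breaks(structure)
    return structure


def write_pdb(structure: Structure, path_or_handle) -> None:
    """Write a Structure back to PDB format (ATOM/TER/END records)."""
    if hasattr(path_or_handle, "write"):
        _write_pdb(structure, path_or_handle)
    else:
        with open(path_or_handle, "w") as handle:
            _write_pdb(structure, handle)


def _format_atom_name(name: str) -> str:
    # element symbol occupies columns 13-14; single-letter-element names of
    # length < 4 are indented by one space
    return f" {name:<3s}" if len(name) < 4 else name


def _write_pdb(structure: Structure, handle) -> None:
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            try:
                resseq = int(res.label) if res.label else res.seq_index
                icode = " "
            except ValueError:
                resseq = int(res.label[:-1])
                icode = res.label[-1]
            for atom in res.atoms.values():
                x, y, z = atom.coords
                handle.write(
                    f"ATOM  {serial:>5d} {_format_atom_name(atom.name)}"
                    f"{atom.altloc or ' '}  {res.code:>1s} {chain.chain_id:>1s}"
                    f"{resseq:>4d}{icode}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.name[0]:>2s}\n")
                serial += 1
        handle.write(f"TER   {serial:>5d}\n")
        serial += 1
    handle.write("END\n")


def structure_to_pdb_string(structure: Structure) -> str:
    buf = io.StringIO()
    write_pdb(structure, buf)
    return buf.getvalue()
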