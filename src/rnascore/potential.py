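"""Training of the distance and torsion statistical potential.

The potential is a pair of inverse-Boltzmann free-energy tables derived
from count histograms over a corpus of structures:

* distance term: for every unordered pair of the 85 atom types, counts of
  inter-residue heavy-atom distances below a 20 Å cutoff in bins of 0.3 Å,
  turned into energies against the *averaged* reference state (the pooled
  distance distribution of all atom-type pairs):

      E_ab(d) = -ln [ (N_ab(d) N) / (N(d) N_ab) ]    (units of k_B T)

* torsion term: the same construction over the seven torsion angles
  (alpha..zeta, chi) in 4.5 degree bins on [0, 360).

Pair admission follows the stacking-aware adjacency rule: atoms in
sequence-adjacent residues of one chain are counted only when both atoms
belong to the bases (adjacent backbones are covalently constrained, but
adjacent bases interact through stacking); residues two or more apart, or
on different chains, always count; same-residue pairs never count.

Distances below the 3 Å clash floor are statistically unreliable; their
bins carry a fixed clash penalty instead of trained values.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .atom_types import (CONVENTION, N_ATOM_TYPES, N_PAIR_TYPES,
                         atom_type_index, is_base_atom, pair_row)
from .errors import ModelFileError
from .geometry import TORSION_NAMES, backbone_torsions
from .structure_io import Structure

log = logging.getLogger(__name__)

FORMAT_VERSION = "rnascore-potential-1"

DEFAULT_BIN_WIDTH = 0.3        # Å
DEFAULT_CUTOFF = 20.0          # Å
DEFAULT_DIHEDRAL_BIN = 4.5     # degrees
DEFAULT_TEMPERATURE = 298.0    # K (recorded; energies are in k_B T units)
DEFAULT_WEIGHT = 3.68          # omega, weight of the torsion term
DEFAULT_E_MAX = 5.0            # k_B T, zero-count bins
DEFAULT_CLASH_PENALTY = 10.0   # k_B T, per atom pair below the clash floor
CLASH_FLOOR = 3.0              # Å


def scott_bin_width(sigma: float, n: int) -> float:
    """Scott's normal-reference bin width, 3.49 sigma N^(-1/3)."""
    if sigma <= 0 or n < 1:
        raise ValueError("sigma must be positive and n >= 1")
    return 3.49 * sigma * n ** (-1.0 / 3.0)


def n_distance_bins(bin_width: float = DEFAULT_BIN_WIDTH,
                    cutoff: float = DEFAULT_CUTOFF) -> int:
    return int(math.ceil(cutoff / bin_width - 1e-9))


def n_dihedral_bins(bin_width: float = DEFAULT_DIHEDRAL_BIN) -> int:
    n = 360.0 / bin_width
    if abs(n - round(n)) > 1e-9:
        raise ValueError("360 must be an integer multiple of the angular bin width")
    return int(round(n))


# ---------------------------------------------------------------------------
# structure flattening and the pair admission rule


@dataclass
class _FlatStructure:
    coords: np.ndarray       # (n, 3)
    type_index: np.ndarray   # (n,) 1-based atom-type index
    residue_ord: np.ndarray  # (n,) global residue ordinal
    chain_ord: np.ndarray    # (n,) chain ordinal
    chain_pos: np.ndarray    # (n,) residue position within its chain
    is_base: np.ndarray      # (n,) bool


def flatten(structure: Structure) -> _FlatStructure:
    coords, types, res_ord, chain_ord, chain_pos, base = [], [], [], [], [], []
    r_ord = 0
    for c_ord, chain in enumerate(structure.chains):
        for pos, res in enumerate(chain.residues):
            for atom in res.atoms.values():
                coords.append(atom.coords)
                types.append(atom_type_index(res.code, atom.name))
                res_ord.append(r_ord)
                chain_ord.append(c_ord)
                chain_pos.append(pos)
                base.append(is_base_atom(res.code, atom.name))
            r_ord += 1
    return _FlatStructure(
        coords=np.asarray(coords, dtype=float).reshape(-1, 3),
        type_index=np.asarray(types, dtype=np.int64),
        residue_ord=np.asarray(res_ord, dtype=np.int64),
        chain_ord=np.asarray(chain_ord, dtype=np.int64),
        chain_pos=np.asarray(chain_pos, dtype=np.int64),
        is_base=np.asarray(base, dtype=bool),
    )


def admissible_pairs(flat: _FlatStructure, cutoff: float):
    """Upper-triangular atom pairs admitted by the adjacency rule, < cutoff.

    Returns (i, j, distances) index arrays.  Sequence-adjacent residues of a
    chain contribute only base-base pairs; same-residue pairs are excluded.
    """
    n = flat.coords.shape[0]
    if n == 0:
        return (np.empty(0, dtype=int),) * 2 + (np.empty(0),)
    delta = flat.coords[:, None, :] - flat.coords[None, :, :]
    dist = np.sqrt((delta * delta).sum(axis=-1))
    iu, ju = np.triu_indices(n, k=1)
    same_res = flat.residue_ord[iu] == flat.residue_ord[ju]
    adjacent = ((flat.chain_ord[iu] == flat.chain_ord[ju])
                & (np.abs(flat.chain_pos[iu] - flat.chain_pos[ju]) == 1))
    both_base = flat.is_base[iu] & flat.is_base[ju]
    keep = (~same_res) & (dist[iu, ju] < cutoff) & (~adjacent | both_base)
    return iu[keep], ju[keep], dist[iu[keep], ju[keep]]


# ---------------------------------------------------------------------------
# count containers


@dataclass
class DistanceCounts:
    """Histogram N_ab(d) over unordered atom-type pairs x distance bins."""

    counts: np.ndarray       # (N_PAIR_TYPES, n_bins) int64
    bin_width: float
    cutoff: float

    @property
    def n_ab(self) -> np.ndarray:       # per-pair totals
        return self.counts.sum(axis=1)

    @property
    def n_d(self) -> np.ndarray:        # per-bin totals, pooled over pairs
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class DihedralCounts:
    """Histogram N_i(theta) over the seven torsion types x angle bins."""

    counts: np.ndarray       # (7, n_bins) int64
    bin_width: float

    @property
    def n_i(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_theta(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def accumulate_distance_counts(structures, bin_width: float = DEFAULT_BIN_WIDTH,
                               cutoff: float = DEFAULT_CUTOFF) -> DistanceCounts:
    """Count admissible atom-pair distances over a corpus."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if cutoff <= CLASH_FLOOR:
        raise ValueError("cutoff must exceed the clash floor")
    n_bins = n_distance_bins(bin_width, cutoff)
    counts = np.zeros((N_PAIR_TYPES, n_bins), dtype=np.int64)
    empty = True
    for structure in structures:
        empty = False
        flat = flatten(structure)
        i, j, dist = admissible_pairs(flat, cutoff)
        if i.size == 0:
            continue
        rows = _pair_rows(flat.type_index[i], flat.type_index[j])
        bins = np.minimum((dist / bin_width).astype(np.int64), n_bins - 1)
        np.add.at(counts, (rows, bins), 1)
    if empty:
        log.warning("empty corpus: distance counts are all zero")
    return DistanceCounts(counts=counts, bin_width=bin_width, cutoff=cutoff)


def _pair_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    i = np.minimum(a, b) - 1
    j = np.maximum(a, b) - 1
    return i * N_ATOM_TYPES - i * (i + 1) // 2 + j


def accumulate_dihedral_counts(structures,
                               bin_width: float = DEFAULT_DIHEDRAL_BIN) -> DihedralCounts:
    """Count defined torsions of each type over a corpus."""
    n_bins = n_dihedral_bins(bin_width)
    counts = np.zeros((len(TORSION_NAMES), n_bins), dtype=np.int64)
    for structure in structures:
        for _, _, torsions in backbone_torsions(structure):
            for row, name in enumerate(TORSION_NAMES):
                theta = getattr(torsions, name)
                if theta is not None:
                    counts[row, min(int(theta / bin_width), n_bins - 1)] += 1
    return DihedralCounts(counts=counts, bin_width=bin_width)


# ---------------------------------------------------------------------------
# Boltzmann inversion


def sippl_smooth(f_pool: np.ndarray, f_row: np.ndarray, m: float,
                 sigma_s: float = 1.0 / 50.0) -> np.ndarray:
    """Sparse-data shrinkage of a row distribution toward the pooled one.

    g = 1/(1+m*sigma) f_pool + m*sigma/(1+m*sigma) f_row: with few
    observations (small m) the row distribution collapses onto the pooled
    reference; with many it converges to the raw row statistics.
    """
    if m < 0:
        raise ValueError("observation count m must be >= 0")
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    f_pool = np.asarray(f_pool, dtype=float)
    f_row = np.asarray(f_row, dtype=float)
    w = m * sigma_s
    g = f_pool / (1.0 + w) + f_row * (w / (1.0 + w))
    total = g.sum()
    return g / total if total > 0 else g


def _pmf_energy(counts: np.ndarray, e_max: float,
                smooth: bool = False, sigma_s: float = 1.0 / 50.0) -> np.ndarray:
    """-ln of (row distribution / pooled distribution), e_max where empty."""
    counts = counts.astype(float)
    row_tot = counts.sum(axis=1, keepdims=True)
    pool = counts.sum(axis=0)
    pool_tot = pool.sum()
    energy = np.full(counts.shape, e_max, dtype=float)
    if pool_tot == 0:
        return energy
    f_pool = pool / pool_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        if smooth:
            for r in range(counts.shape[0]):
                if row_tot[r, 0] == 0:
                    continue
                f_row = counts[r] / row_tot[r, 0]
                g = sippl_smooth(f_pool, f_row, m=row_tot[r, 0], sigma_s=sigma_s)
                e = -np.log(g / f_pool)
                energy[r] = np.where(np.isfinite(e), e, e_max)
        else:
            f_obs = counts / row_tot
            e = -np.log(f_obs / f_pool)
            energy = np.where(np.isfinite(e), e, e_max)
    return energy


@dataclass
class PotentialModel:
    """Trained energy tables plus every hyper-parameter needed to score."""

    distance_energy: np.ndarray   # (N_PAIR_TYPES, n_distance_bins), k_B T
    dihedral_energy: np.ndarray   # (7, n_dihedral_bins), k_B T
    bin_width: float = DEFAULT_BIN_WIDTH
    cutoff: float = DEFAULT_CUTOFF
    dihedral_bin_width: float = DEFAULT_DIHEDRAL_BIN
    temperature: float = DEFAULT_TEMPERATURE
    weight: float = DEFAULT_WEIGHT
    e_max: float = DEFAULT_E_MAX
    clash_penalty: float = DEFAULT_CLASH_PENALTY
    clash_floor: float = CLASH_FLOOR
    convention: str = CONVENTION
    provenance: str = ""

    @property
    def n_penalty_bins(self) -> int:
        # bins whose upper edge is at or below the clash floor
        return int(math.floor(self.clash_floor / self.bin_width + 1e-9))

    def pair_energy(self, a: int, b: int, distance: float) -> float:
        """Energy of one typed atom pair at a given distance (k_B T)."""
        if distance >= self.cutoff:
            return 0.0
        k = min(int(distance / self.bin_width), self.distance_energy.shape[1] - 1)
        return float(self.distance_energy[pair_row(a, b), k])


def distance_energy_table(counts: DistanceCounts,
                          e_max: float = DEFAULT_E_MAX,
                          clash_penalty: float = DEFAULT_CLASH_PENALTY,
                          smooth: bool = False,
                          sigma_s: float = 1.0 / 50.0) -> np.ndarray:
    """Boltzmann inversion of distance counts against the averaged reference.

    Bins wholly below the clash floor get the fixed clash penalty; bins the
    corpus never populated get ``e_max``.
    """
    energy = _pmf_energy(counts.counts, e_max, smooth=smooth, sigma_s=sigma_s)
    n_penalty = int(math.floor(CLASH_FLOOR / counts.bin_width + 1e-9))
    energy[:, :n_penalty] = clash_penalty
    return energy


def dihedral_energy_table(counts: DihedralCounts,
                          e_max: float = DEFAULT_E_MAX) -> np.ndarray:
    """Boltzmann inversion of torsion counts against the pooled reference."""
    return _pmf_energy(counts.counts, e_max)


def train(structures, bin_width: float = DEFAULT_BIN_WIDTH,
          cutoff: float = DEFAULT_CUTOFF,
          dihedral_bin_width: float = DEFAULT_DIHEDRAL_BIN,
          weight: float = DEFAULT_WEIGHT,
          e_max: float = DEFAULT_E_MAX,
          clash_penalty: float = DEFAULT_CLASH_PENALTY,
          smooth: bool = False, sigma_s: float = 1.0 / 50.0,
          provenance: str = "") -> PotentialModel:
    """Train a full potential from a corpus of structures."""
    structures = list(structures)
    d_counts = accumulate_distance_counts(structures, bin_width, cutoff)
    t_counts = accumulate_dihedral_counts(structures, dihedral_bin_width)
    return PotentialModel(
        distance_energy=distance_energy_table(d_counts, e_max, clash_penalty,
                                              smooth=smooth, sigma_s=sigma_s),
        dihedral_energy=dihedral_energy_table(t_counts, e_max),
        bin_width=bin_width, cutoff=cutoff,
        dihedral_bin_width=dihedral_bin_width,
        weight=weight, e_max=e_max, clash_penalty=clash_penalty,
        provenance=provenance or f"trained on {len(structures)} structures",
    )


# ---------------------------------------------------------------------------
# persistence: plain-text parameter file


def save_model(model: PotentialModel, path) -> None:
    """Write a parameter file: key-value header, then the two tables.

    Energies are printed with 17 significant digits, so a load reproduces
    them bit-exactly; a checksum over the data section guards truncation
    and corruption.
    """
    d_lines = []
    n_rows, n_bins = model.distance_energy.shape
    idx = 0
    for a in range(1, N_ATOM_TYPES + 1):
        for b in range(a, N_ATOM_TYPES + 1):
            row = model.distance_energy[idx]
            for k in range(n_bins):
                d_lines.append(f"{a} {b} {k} {row[k]:.17g}")
            idx += 1
    t_lines = []
    for r, name in enumerate(TORSION_NAMES):
        for k in range(model.dihedral_energy.shape[1]):
            t_lines.append(f"{name} {k} {model.dihedral_energy[r, k]:.17g}")
    body = "\n".join(d_lines + t_lines) + "\n"
    checksum = hashlib.sha256(body.encode()).hexdigest()
    header = [
        f"format_version: {FORMAT_VERSION}",
        f"atom_convention: {model.convention}",
        f"bin_width: {model.bin_width:.17g}",
        f"cutoff: {model.cutoff:.17g}",
        f"dihedral_bin_width: {model.dihedral_bin_width:.17g}",
        f"temperature: {model.temperature:.17g}",
        f"weight: {model.weight:.17g}",
        f"e_max: {model.e_max:.17g}",
        f"clash_penalty: {model.clash_penalty:.17g}",
        f"clash_floor: {model.clash_floor:.17g}",
        f"n_distance_rows: {n_rows}",
        f"n_distance_bins: {n_bins}",
        f"n_dihedral_bins: {model.dihedral_energy.shape[1]}",
        f"provenance: {model.provenance}",
        f"checksum: {checksum}",
        "[data]",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write(body)


def load_model(path) -> PotentialModel:
    """Read a parameter file written by :func:`save_model`.

    Raises :class:`ModelFileError` on version mismatch, truncation or
    checksum failure; no partial model is ever returned.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        header_text, body = text.split("[data]\n", 1)
    except ValueError:
        raise ModelFileError("missing data section (truncated file?)") from None
    header = {}
    for line in header_text.strip().splitlines():
        key, _, value = line.partition(":")
        header[key.strip()] = value.strip()
    if header.get("format_version") != FORMAT_VERSION:
        raise ModelFileError(
            f"unsupported format version {header.get('format_version')!r}")
    if header.get("atom_convention") != CONVENTION:
        raise ModelFileError(
            f"atom-type numbering convention mismatch: {header.get('atom_convention')!r}")
    checksum = hashlib.sha256(body.encode()).hexdigest()
    if checksum != header.get("checksum"):
        raise ModelFileError("checksum mismatch: file is truncated or corrupt")
    try:
        n_rows = int(header["n_distance_rows"])
        n_bins = int(header["n_distance_bins"])
        n_tbins = int(header["n_dihedral_bins"])
    except KeyError as exc:
        raise ModelFileError(f"missing header key {exc}") from None
    if n_rows != N_PAIR_TYPES:
        raise ModelFileError(f"expected {N_PAIR_TYPES} pair rows, file has {n_rows}")

    lines = body.splitlines()
    expected = n_rows * n_bins + len(TORSION_NAMES) * n_tbins
    if len(lines) != expected:
        raise ModelFileError(
            f"truncated data section: {len(lines)} lines, expected {expected}")
    d_part = lines[:n_rows * n_bins]
    darr = np.empty((n_rows, n_bins), dtype=float)
    idx = 0
    row = 0
    for a in range(1, N_ATOM_TYPES + 1):
        for b in range(a, N_ATOM_TYPES + 1):
            for k in range(n_bins):
                fields = d_part[idx].split()
                if (int(fields[0]), int(fields[1]), int(fields[2])) != (a, b, k):
                    raise ModelFileError(f"unexpected distance row at line {idx}")
                darr[row, k] = float(fields[3])
                idx += 1
            row += 1
    tarr = np.empty((len(TORSION_NAMES), n_tbins), dtype=float)
    t_part = lines[n_rows * n_bins:]
    idx = 0
    for r, name in enumerate(TORSION_NAMES):
        for k in range(n_tbins):
            fields = t_part[idx].split()
            if fields[0] != name or int(fields[1]) != k:
                raise ModelFileError(f"unexpected dihedral row at line {idx}")
            tarr[r, k] = float(fields[2])
            idx += 1
    return PotentialModel(
        distance_energy=darr, dihedral_energy=tarr,
        bin_width=float(header["bin_width"]), cutoff=float(header["cutoff"]),
        dihedral_bin_width=float(header["dihedral_bin_width"]),
        temperature=float(header["temperature"]),
        weight=float(header["weight"]), e_max=float(header["e_max"]),
        clash_penalty=float(header["clash_penalty"]),
        clash_floor=float(header["clash_floor"]),
        convention=header["atom_convention"],
        provenance=header.get("provenance", ""),
    )
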