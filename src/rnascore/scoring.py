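"""Evaluation of structures under a trained potential.

The total score is the weighted combination of the two terms,

    E_total = E_distance + omega * E_dihedral,

with the shipped default omega = 3.68.  Scoring admits exactly the atom
pairs admitted during training (shared code path), so the inverse-Boltzmann
construction compares like with like; atom pairs below the 3 Å clash floor
contribute the fixed clash penalty and are reported separately as clashes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import TORSION_NAMES, backbone_torsions
from .potential import PotentialModel, _pair_rows, admissible_pairs, flatten
from .structure_io import Structure

log = logging.getLogger(__name__)


@dataclass
class ScoreResult:
    """Total energy and its decomposition for one structure (k_B T units)."""

    total: float
    distance_term: float
    dihedral_term: float
    clash_count: int
    n_pairs_scored: int
    n_torsions_scored: int


def score_distance(structure: Structure,
                   model: PotentialModel) -> tuple[float, int, int]:
    """Distance-term energy, clash count and number of scored pairs."""
    flat = flatten(structure)
    if structure.n_residues < 2:
        log.warning("structure %s has < 2 scoreable residues", structure.source_id)
        return 0.0, 0, 0
    i, j, dist = admissible_pairs(flat, model.cutoff)
    if i.size == 0:
        return 0.0, 0, 0
    rows = _pair_rows(flat.type_index[i], flat.type_index[j])
    bins = np.minimum((dist / model.bin_width).astype(np.int64),
                      model.distance_energy.shape[1] - 1)
    energies = model.distance_energy[rows, bins]
    clash_count = int((dist < model.clash_floor).sum())
    return float(energies.sum()), clash_count, int(i.size)


def score_dihedral(structure: Structure,
                   model: PotentialModel) -> tuple[float, int]:
    """Torsion-term energy and number of scored torsions."""
    n_bins = model.dihedral_energy.shape[1]
    total = 0.0
    n_scored = 0
    for _, _, torsions in backbone_torsions(structure):
        for row, name in enumerate(TORSION_NAMES):
            theta = getattr(torsions, name)
            if theta is None:
                continue
            k = min(int(theta / model.dihedral_bin_width), n_bins - 1)
            total += float(model.dihedral_energy[row, k])
            n_scored += 1
    return total, n_scored


def score_total(structure: Structure, model: PotentialModel,
                normalize_per_residue: bool = False) -> ScoreResult:
    """Weighted total energy E_distance + omega * E_dihedral.

    Scores are raw sums by default (decoys of one RNA are compared);
    ``normalize_per_residue`` divides both terms by the residue count for
    cross-RNA comparisons.
    """
    distance_term, clash_count, n_pairs = score_distance(structure, model)
    dihedral_term, n_torsions = score_dihedral(structure, model)
    if normalize_per_residue and structure.n_residues > 0:
        distance_term /= structure.n_residues
        dihedral_term /= structure.n_residues
    return ScoreResult(
        total=distance_term + model.weight * dihedral_term,
        distance_term=distance_term, dihedral_term=dihedral_term,
        clash_count=clash_count, n_pairs_scored=n_pairs,
        n_torsions_scored=n_torsions)


def residue_pair_energy(structure: Structure, model: PotentialModel,
                        i: tuple[int, int], j: tuple[int, int],
                        base_only: bool = False) -> float:
    """Distance energy between two residues, addressed as (chain, residue).

    Both indices are 0-based positions (chain index, residue index within
    the chain).  With ``base_only`` the sum is restricted to base-base atom
    pairs, which isolates the pairing/stacking part of the interaction.
    The admission rule matches training, so summing this quantity over all
    residue pairs reproduces the distance term exactly.
    """
    if i == j:
        raise ValueError("residue indices must differ")
    flat = flatten(structure)
    # map (chain, residue) to the global residue ordinal
    sizes = [len(c.residues) for c in structure.chains]
    for (ci, ri) in (i, j):
        if not (0 <= ci < len(sizes)) or not (0 <= ri < sizes[ci]):
            raise IndexError(f"no residue at {(ci, ri)}")
    offs = np.cumsum([0] + sizes)
    ga = offs[i[0]] + i[1]
    gb = offs[j[0]] + j[1]
    ii, jj, dist = admissible_pairs(flat, model.cutoff)
    ra, rb = flat.residue_ord[ii], flat.residue_ord[jj]
    keep = ((ra == ga) & (rb == gb)) | ((ra == gb) & (rb == ga))
    if base_only:
        keep &= flat.is_base[ii] & flat.is_base[jj]
    if not keep.any():
        return 0.0
    rows = _pair_rows(flat.type_index[ii[keep]], flat.type_index[jj[keep]])
    bins = np.minimum((dist[keep] / model.bin_width).astype(np.int64),
                      model.distance_energy.shape[1] - 1)
    return float(model.distance_energy[rows, bins].sum())


def stacking_profile(structure: Structure, model: PotentialModel,
                     chain: int = 0) -> list[tuple[str, float]]:
    """Base-stacking energies of consecutive residues along one chain."""
    out = []
    residues = structure.chains[chain].residues
    for k in range(len(residues) - 1):
        e = residue_pair_energy(structure, model, (chain, k), (chain, k + 1),
                                base_only=True)
        out.append((f"{residues[k].label}-{residues[k + 1].label}", e))
    return out


def pairing_profile(structure: Structure, model: PotentialModel,
                    ) -> list[tuple[str, float]]:
    """Base-pairing energies between all non-adjacent residue pairs.

    Sorted ascending, so hydrogen-bonded partners surface at the top of the
    list; the complement of the stacking profile for network analyses.
    """
    out = []
    sizes = [len(c.residues) for c in structure.chains]
    refs = [(ci, ri) for ci, n in enumerate(sizes) for ri in range(n)]
    for a in range(len(refs)):
        for b in range(a + 1, len(refs)):
            (ca, ra), (cb, rb) = refs[a], refs[b]
            if ca == cb and abs(ra - rb) == 1:
                continue
            e = residue_pair_energy(structure, model, refs[a], refs[b],
                                    base_only=True)
            if e != 0.0:
                la = structure.chains[ca].residues[ra].label
                lb = structure.chains[cb].residues[rb].label
                out.append((f"{structure.chains[ca].chain_id}:{la}-"
                            f"{structure.chains[cb].chain_id}:{lb}", e))
    return sorted(out, key=lambda t: t[1])
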