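"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from rnascore import FixtureSpec, make_fixture, make_training_corpus, train
from rnascore.atom_types import BACKBONE_ATOMS, atom_type_index, pair_row
from rnascore.structure_io import Atom, Chain, Residue, Structure, flag_chain_breaks


# ---------------------------------------------------------------------------
# brute-force oracles (independent re-statements of the counting rules)


def oracle_atom_list(structure):
    """Flat (chain_idx, pos, code, name, coords, is_base) list, file order."""
    out = []
    for ci, chain in enumerate(structure.chains):
        for pos, res in enumerate(chain.residues):
            for name, atom in res.atoms.items():
                out.append((ci, pos, res.code, name, atom.coords,
                            name not in BACKBONE_ATOMS))
    return out


def oracle_pair_iter(structure, cutoff):
    """Enumerate admissible atom pairs by direct nested loops.

    Independent restatement of the admission rule: distinct residues,
    distance below cutoff, and sequence-adjacent same-chain residues admit
    only base-base pairs.
    """
    atoms = oracle_atom_list(structure)
    for a in range(len(atoms)):
        ci, pi, code_i, name_i, xyz_i, base_i = atoms[a]
        for b in range(a + 1, len(atoms)):
            cj, pj, code_j, name_j, xyz_j, base_j = atoms[b]
            if ci == cj and pi == pj:
                continue
            if ci == cj and abs(pi - pj) == 1 and not (base_i and base_j):
                continue
            d = math.dist(xyz_i, xyz_j)
            if d < cutoff:
                yield (code_i, name_i, code_j, name_j, d)


def oracle_distance_counts(structures, bin_width, cutoff, n_rows, n_bins):
    counts = np.zeros((n_rows, n_bins), dtype=np.int64)
    for s in structures:
        for code_i, name_i, code_j, name_j, d in oracle_pair_iter(s, cutoff):
            row = pair_row(atom_type_index(code_i, name_i),
                           atom_type_index(code_j, name_j))
            counts[row, min(int(d / bin_width), n_bins - 1)] += 1
    return counts


def oracle_distance_score(structure, model):
    """Sum of table lookups over the oracle's own admissible-pair stream."""
    total = 0.0
    n_bins = model.distance_energy.shape[1]
    for code_i, name_i, code_j, name_j, d in oracle_pair_iter(structure,
                                                              model.cutoff):
        row = pair_row(atom_type_index(code_i, name_i),
                       atom_type_index(code_j, name_j))
        total += model.distance_energy[row, min(int(d / model.bin_width),
                                                n_bins - 1)]
    return total


def oracle_torsion(p1, p2, p3, p4):
    """Dihedral via the angle between plane normals, signed by triple product."""
    p1, p2, p3, p4 = map(np.asarray, (p1, p2, p3, p4))
    n1 = np.cross(p2 - p1, p3 - p2)
    n2 = np.cross(p3 - p2, p4 - p3)
    n1 = n1 / np.linalg.norm(n1)
    n2 = n2 / np.linalg.norm(n2)
    cosang = np.clip(np.dot(n1, n2), -1.0, 1.0)
    ang = math.degrees(math.acos(cosang))
    if np.dot(np.cross(n1, n2), p3 - p2) < 0:
        ang = -ang
    return ang % 360.0


def oracle_defined_torsions(structure):
    """Independent scan yielding (angle name, value) for every residue.

    Re-states the torsion definitions directly: neighbour atoms are used
    only across intact (non-broken) junctions, chi uses the purine or
    pyrimidine quadruple, and any missing atom leaves the angle undefined.
    """
    purine_chi = ("O4'", "C1'", "N9", "C4")
    pyrimidine_chi = ("O4'", "C1'", "N1", "C2")
    for chain in structure.chains:
        n = len(chain.residues)
        for i, res in enumerate(chain.residues):
            prev_res = chain.residues[i - 1] if i > 0 and chain.is_linked(i - 1) else None
            next_res = chain.residues[i + 1] if i < n - 1 and chain.is_linked(i) else None

            def emit(name, quad):
                if any(q is None for q in quad):
                    return
                a, b, c, d = quad
                if (np.linalg.norm(np.cross(b - a, c - b)) < 1e-10
                        or np.linalg.norm(np.cross(c - b, d - c)) < 1e-10):
                    return
                yield_list.append((name, oracle_torsion(a, b, c, d)))

            yield_list = []
            if prev_res is not None:
                emit("alpha", (prev_res.coord("O3'"), res.coord("P"),
                               res.coord("O5'"), res.coord("C5'")))
            emit("beta", (res.coord("P"), res.coord("O5'"), res.coord("C5'"),
                          res.coord("C4'")))
            emit("gamma", (res.coord("O5'"), res.coord("C5'"), res.coord("C4'"),
                           res.coord("C3'")))
            emit("delta", (res.coord("C5'"), res.coord("C4'"), res.coord("C3'"),
                           res.coord("O3'")))
            if next_res is not None:
                emit("epsilon", (res.coord("C4'"), res.coord("C3'"),
                                 res.coord("O3'"), next_res.coord("P")))
                emit("zeta", (res.coord("C3'"), res.coord("O3'"),
                              next_res.coord("P"), next_res.coord("O5'")))
            quad = purine_chi if res.code in "AG" else pyrimidine_chi
            emit("chi", tuple(res.coord(a) for a in quad))
            yield from yield_list


def oracle_dihedral_counts(structure, bin_width, names):
    counts = np.zeros((len(names), int(round(360.0 / bin_width))), dtype=np.int64)
    n_bins = counts.shape[1]
    for name, theta in oracle_defined_torsions(structure):
        counts[names.index(name), min(int(theta / bin_width), n_bins - 1)] += 1
    return counts


def oracle_dihedral_score(structure, model, names):
    total = 0.0
    n_bins = model.dihedral_energy.shape[1]
    for name, theta in oracle_defined_torsions(structure):
        total += model.dihedral_energy[
            names.index(name), min(int(theta / model.dihedral_bin_width), n_bins - 1)]
    return total


def random_rigid_motion(rng):
    """A uniformly random proper rotation plus a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
    return rot, rng.uniform(-20, 20, 3)


def transform_structure(structure, rot, shift):
    moved = Structure(source_id=structure.source_id,
                      model_index=structure.model_index)
    for chain in structure.chains:
        new_chain = Chain(chain_id=chain.chain_id, breaks=set(chain.breaks))
        for res in chain.residues:
            new_res = Residue(code=res.code, seq_index=res.seq_index,
                              label=res.label)
            for name, atom in res.atoms.items():
                new_res.atoms[name] = Atom(name=name,
                                           coords=rot @ atom.coords + shift)
            new_chain.residues.append(new_res)
        moved.chains.append(new_chain)
    return moved


def random_small_fixture(seed, max_len=10):
    """A random single-strand or duplex fixture of 5-20 residues total."""
    rng = np.random.default_rng(seed)
    topology = "duplex" if rng.integers(2) else "single"
    length = int(rng.integers(5, max_len + 1))
    spec = FixtureSpec(topology=topology, length=length, noise_sigma=0.1,
                       seed=seed, twist=float(rng.uniform(29, 35)),
                       rise=float(rng.uniform(3.1, 3.5)))
    return make_fixture(spec)[0]


def toy_residue(code, atoms, seq_index=1, label=None):
    """Build a residue from {name: coords} without geometric validation."""
    res = Residue(code=code, seq_index=seq_index, label=label or str(seq_index))
    for name, xyz in atoms.items():
        res.atoms[name] = Atom(name=name, coords=np.asarray(xyz, dtype=float))
    return res


def toy_structure(chains):
    """chains: list of (chain_id, [Residue, ...])."""
    s = Structure(chains=[Chain(chain_id=cid, residues=list(residues))
                          for cid, residues in chains])
    flag_chain_breaks(s)
    return s


# ---------------------------------------------------------------------------
# session fixtures


@pytest.fixture(scope="session")
def trained_model():
    """A potential trained on the default synthetic corpus."""
    return train(make_training_corpus(30, seed=7),
                 provenance="test corpus n=30 seed=7")


@pytest.fixture(scope="session")
def duplex_fixture():
    return make_fixture(FixtureSpec("duplex", 6, "GAUCGA", seed=11))


@pytest.fixture(scope="session")
def hairpin_fixture():
    return make_fixture(FixtureSpec("hairpin", 12, seed=13))
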