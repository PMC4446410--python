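"""Torsion angles and optimal-superposition RMSD.

The seven torsions scored by the potential are the six backbone angles
α, β, γ, δ, ε, ζ and the glycosidic angle χ, with the IUPAC atom
quadruples:

    α(i) = O3'(i-1)-P(i)-O5'(i)-C5'(i)
    β(i) = P-O5'-C5'-C4'          γ(i) = O5'-C5'-C4'-C3'
    δ(i) = C5'-C4'-C3'-O3'        ε(i) = C4'-C3'-O3'-P(i+1)
    ζ(i) = C3'-O3'-P(i+1)-O5'(i+1)
    χ(i) = O4'-C1'-N9-C4 (purines) / O4'-C1'-N1-C2 (pyrimidines)

Angles are reported in degrees on [0, 360) with 0° = cis (eclipsed).
Any torsion that spans a flagged chain break, or whose atoms are missing,
is undefined (None).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import DegenerateGeometryError, InsufficientCorrespondenceError
from .structure_io import Structure

TORSION_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")

_DEGENERACY_TOL = 1e-10


def torsion(p1, p2, p3, p4) -> float:
    """Signed dihedral about the p2-p3 axis, in degrees on [0, 360).

    Raises :class:`DegenerateGeometryError` for coincident consecutive
    points or collinear bond vectors.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p2 - p1
    b1 = p3 - p2
    b2 = p4 - p3
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    norm_b1 = np.linalg.norm(b1)
    if (np.linalg.norm(n1) < _DEGENERACY_TOL or np.linalg.norm(n2) < _DEGENERACY_TOL
            or norm_b1 < _DEGENERACY_TOL):
        raise DegenerateGeometryError("collinear or coincident points")
    y = np.dot(np.cross(n1, n2), b1 / norm_b1)
    x = np.dot(n1, n2)
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


@dataclass
class TorsionSet:
    """Per-residue torsions in degrees on [0, 360); None where undefined."""

    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    delta: float | None = None
    epsilon: float | None = None
    zeta: float | None = None
    chi: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def defined(self) -> dict[str, float]:
        return {k: v for k, v in self.as_dict().items() if v is not None}


def _try_torsion(*points) -> float | None:
    if any(p is None for p in points):
        return None
    try:
        return torsion(*points)
    except DegenerateGeometryError:
        return None


def backbone_torsions(structure: Structure) -> list[tuple[object, object, TorsionSet]]:
    """Compute the seven torsions for every residue.

    Returns a list of (chain, residue, TorsionSet) in file order.  Boundary
    residues lack the neighbours needed for α (first) and ε/ζ (last), and a
    flagged chain break makes every torsion spanning it undefined.
    """
    out = []
    for chain in structure.chains:
        n = len(chain.residues)
        for i, res in enumerate(chain.residues):
            prev_res = chain.residues[i - 1] if i > 0 and chain.is_linked(i - 1) else None
            next_res = chain.residues[i + 1] if i < n - 1 and chain.is_linked(i) else None
            ts = TorsionSet()
            p, o5, c5, c4 = (res.coord(a) for a in ("P", "O5'", "C5'", "C4'"))
            c3, o3 = res.coord("C3'"), res.coord("O3'")
            if prev_res is not None:
                ts.alpha = _try_torsion(prev_res.coord("O3'"), p, o5, c5)
            ts.beta = _try_torsion(p, o5, c5, c4)
            ts.gamma = _try_torsion(o5, c5, c4, c3)
            ts.delta = _try_torsion(c5, c4, c3, o3)
            if next_res is not None:
                np_ = next_res.coord("P")
                ts.epsilon = _try_torsion(c4, c3, o3, np_)
                ts.zeta = _try_torsion(c3, o3, np_, next_res.coord("O5'"))
            if res.code in ("A", "G"):
                ts.chi = _try_torsion(res.coord("O4'"), res.coord("C1'"),
                                      res.coord("N9"), res.coord("C4"))
            else:
                ts.chi = _try_torsion(res.coord("O4'"), res.coord("C1'"),
                                      res.coord("N1"), res.coord("C2"))
            out.append((chain, res, ts))
    return out


def kabsch_rmsd(coords_a, coords_b) -> float:
    """RMSD after optimal rigid superposition (Kabsch, proper rotation).

    *coords_a* and *coords_b* are matched (n, 3) coordinate arrays, n >= 3.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must be matched (n, 3)")
    if a.shape[0] < 3:
        raise InsufficientCorrespondenceError(
            f"need >= 3 matched atoms, got {a.shape[0]}")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    diff = a @ rot.T - b
    return float(np.sqrt((diff * diff).sum() / a.shape[0]))


def matched_coords(ref: Structure, model: Structure,
                   atom_filter=None) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates matched by (chain position, residue position, atom name).

    The intersection of the two structures' atom sets, in the reference's
    order.  *atom_filter* optionally restricts names (e.g. C4'-only RMSD).
    """
    ref_coords, mdl_coords = [], []
    for (ca, cb) in zip(ref.chains, model.chains):
        for (ra, rb) in zip(ca.residues, cb.residues):
            for name, atom in ra.atoms.items():
                if atom_filter is not None and name not in atom_filter:
                    continue
                other = rb.atoms.get(name)
                if other is not None:
                    ref_coords.append(atom.coords)
                    mdl_coords.append(other.coords)
    if not ref_coords:
        raise InsufficientCorrespondenceError("no matched atoms")
    return np.array(ref_coords), np.array(mdl_coords)


def structure_rmsd(ref: Structure, model: Structure, atom_filter=None) -> float:
    """All-heavy-atom Kabsch RMSD between two conformers of one RNA (Å).

    Pass ``atom_filter={"C4'"}`` for a backbone-trace RMSD.
    """
    a, b = matched_coords(ref, model, atom_filter)
    return kabsch_rmsd(a, b)
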