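"""Deterministic generator of RNA-like structures and decoy ensembles.

Every other module is testable without external data because this module
emits small structures that carry exactly the canonical heavy-atom set of
each residue, plausible bond geometry, and a declared ground truth of
base-pair and base-stack contacts.

The geometry is idealized, not physical: bases are exactly planar rings
placed on a regular helical scaffold with their normals along the helix
axis, Watson-Crick partners are coplanar with a fixed glycosidic-anchor
construction (C1'-C1' 10.5 Å, 54.5° glycosidic angles, giving an
invariant N9-purine to N1-pyrimidine separation of ~8.8 Å across a pair),
and the sugar-phosphate moiety is a rigid idealized ribose unit whose
rotation about the glycosidic axis is chosen per residue to close the
O3'-P backbone linkage.  Helical twist and rise can be jittered per
structure to emulate conformational diversity in a training corpus; the
within-pair geometry is unaffected by that jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .atom_types import BASE_ATOMS
from .structure_io import Atom, Chain, Residue, Structure, flag_chain_breaks
from .geometry import structure_rmsd

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: default helical parameters (degrees, Å)
DEFAULT_TWIST = 32.7
DEFAULT_RISE = 3.2
#: glycosidic-anchor pair construction constants (Å, degrees)
C1_C1_DISTANCE = 10.5
GLYCOSIDIC_ANGLE = 54.5
#: invariant separation of the two glycosidic nitrogens across every pair
#: family (Å); this is the signature distance whose sharp population the
#: trained potential recovers as a base-pairing energy minimum
GLYCOSIDIC_NN = C1_C1_DISTANCE - 2 * 1.47 * math.cos(math.radians(GLYCOSIDIC_ANGLE))
#: minimum heavy-atom contact across a base pair (Å): keeps every contact
#: above the 3 Å clash floor of the potential
PAIR_CONTACT_TARGET = 3.05
#: ceiling for the closest polar-polar contact (Å): keeps the pair
#: detectable by the 3.5 Å hydrogen-bond criterion of the annotation module
PAIR_HBOND_CEILING = 3.40


# ---------------------------------------------------------------------------
# base templates: planar coordinates with glycosidic N at the origin and the
# C1'->N direction along +x (C1' at (-1.47, 0, 0)); ring extends into +x.


def _hexagon(center, start_angle_deg, step_deg, n=6, radius=1.38):
    pts = []
    for k in range(n):
        a = math.radians(start_angle_deg + k * step_deg)
        pts.append(np.array([center[0] + radius * math.cos(a),
                             center[1] + radius * math.sin(a), 0.0]))
    return pts


def _pyrimidine_template(code: str) -> dict[str, np.ndarray]:
    center = (1.38, 0.0)
    ring = _hexagon(center, 180.0, 60.0)  # N1 C2 N3 C4 C5 C6 counter-clockwise
    names = ("N1", "C2", "N3", "C4", "C5", "C6")
    atoms = dict(zip(names, ring))
    # exocyclic atoms point radially out of the ring
    def _exo(base_atom, length):
        p = atoms[base_atom]
        d = p - np.array([center[0], center[1], 0.0])
        return p + length * d / np.linalg.norm(d)
    atoms["O2"] = _exo("C2", 1.23)
    atoms["O4" if code == "U" else "N4"] = _exo("C4", 1.23 if code == "U" else 1.34)
    atoms["C1'"] = np.array([-1.47, 0.0, 0.0])
    return atoms


def _purine_template(code: str) -> dict[str, np.ndarray]:
    r5 = 1.38 / (2.0 * math.sin(math.pi / 5.0))
    p_center = np.array([r5, 0.0, 0.0])
    # five-ring N9 C4 C5 N7 C8 with the fused edge C4-C5 on the -y side so
    # that the Watson-Crick edge of the hexagon faces the partner base
    angles = {"N9": 180.0, "C4": -108.0, "C5": -36.0, "N7": 36.0, "C8": 108.0}
    atoms = {name: p_center + r5 * np.array([math.cos(math.radians(a)),
                                             math.sin(math.radians(a)), 0.0])
             for name, a in angles.items()}
    # hexagon fused on C4-C5, center on the side away from the pentagon
    c4, c5 = atoms["C4"], atoms["C5"]
    mid = 0.5 * (c4 + c5)
    edge = (c5 - c4) / np.linalg.norm(c5 - c4)
    perp = np.array([edge[1], -edge[0], 0.0])
    if np.dot(mid + perp - p_center, mid + perp - p_center) < np.dot(mid - perp - p_center, mid - perp - p_center):
        perp = -perp
    h_center = mid + 1.38 * math.cos(math.pi / 6.0) * perp
    a4 = math.degrees(math.atan2(c4[1] - h_center[1], c4[0] - h_center[0]))
    a5 = math.degrees(math.atan2(c5[1] - h_center[1], c5[0] - h_center[0]))
    step = 60.0 if ((a5 - a4) % 360.0 + 360.0) % 360.0 < 180.0 else -60.0
    hexnames = ("C4", "N3", "C2", "N1", "C6", "C5")  # C4 ... C5 around
    for k, name in enumerate(hexnames):
        a = math.radians(a4 - step * k)
        atoms[name] = h_center + 1.38 * np.array([math.cos(a), math.sin(a), 0.0])

    def _exo(base_atom, length):
        p = atoms[base_atom]
        d = p - h_center
        return p + length * d / np.linalg.norm(d)
    if code == "A":
        atoms["N6"] = _exo("C6", 1.34)
    else:
        atoms["O6"] = _exo("C6", 1.23)
        atoms["N2"] = _exo("C2", 1.34)
    atoms["C1'"] = np.array([-1.47, 0.0, 0.0])
    return atoms


_TEMPLATES = {"A": _purine_template("A"), "G": _purine_template("G"),
              "U": _pyrimidine_template("U"), "C": _pyrimidine_template("C")}

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "U": "N1", "C": "N1"}


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_FLIP_X = np.diag([1.0, -1.0, -1.0])  # 180 degree rotation about x


def _base_atom_names(code: str) -> tuple[str, ...]:
    return BASE_ATOMS[code]


def _place_base(code: str, n_pos: np.ndarray, rot: np.ndarray) -> dict[str, np.ndarray]:
    """Rigidly place a base template: rotation *rot*, glycosidic N at *n_pos*."""
    tpl = _TEMPLATES[code]
    return {name: rot @ xyz + n_pos for name, xyz in tpl.items()}


def _pair_geometry(code_left: str):
    """Coordinates of a coplanar WC-style pair in the pair frame (z = 0 plane).

    Returns (atoms_left, atoms_right, code_right).  The left base keeps its
    chirality; the right base is flipped (antiparallel partner).  Each base is
    rotated in-plane about its glycosidic N until the closest heavy-atom
    contact across the pair reaches :data:`PAIR_CONTACT_TARGET`; this leaves
    the glycosidic-N separation (the base-pairing signature distance) fixed.
    """
    code_right = COMPLEMENT[code_left]
    half = C1_C1_DISTANCE / 2.0
    c1_left = np.array([-half, 0.0, 0.0])
    # the A-U family pins its glycosidic N-N separation at the canonical
    # signature distance (the attachment angle absorbs any slide); the G-C
    # family keeps the canonical attachment angle and lets N-N float, since
    # its bulkier exocyclic rim cannot close to the same separation
    preserve_nn = code_left in ("A", "U")

    def _attach_angle(shift: float) -> float:
        if preserve_nn:
            c1c1 = C1_C1_DISTANCE + shift
            return math.degrees(math.acos((c1c1 - GLYCOSIDIC_NN) / (2 * 1.47)))
        return GLYCOSIDIC_ANGLE

    polar_left = [i for i, n in enumerate(_base_atom_names(code_left)) if n[0] in "NO"]
    polar_right = [i for i, n in enumerate(_base_atom_names(code_right)) if n[0] in "NO"]

    def build(rho_l: float, rho_r: float, shift: float):
        # C1' anchors sit at a fixed separation plus the family's outward
        # slide; the glycosidic attachment angle is then solved so that the
        # glycosidic N-N separation (the base-pairing signature distance)
        # keeps its canonical value regardless of the slide.  The opening
        # rotations spin only the bases about their glycosidic nitrogens.
        ang = _attach_angle(shift)
        c1_right = np.array([half + shift, 0.0, 0.0])
        n_left = c1_left + 1.47 * np.array([math.cos(math.radians(ang)),
                                            math.sin(math.radians(ang)), 0.0])
        n_right = c1_right + 1.47 * np.array([-math.cos(math.radians(ang)),
                                              math.sin(math.radians(ang)), 0.0])
        left = _place_base(code_left, n_left, _rot_z(ang + rho_l))
        left["C1'"] = c1_left.copy()
        right = _place_base(code_right, n_right,
                            _rot_z(180.0 - ang - rho_r) @ _FLIP_X)
        right["C1'"] = c1_right
        return left, right

    tpl_l = np.array([_TEMPLATES[code_left][n] for n in _base_atom_names(code_left)])
    tpl_r = np.array([_TEMPLATES[code_right][n] for n in _base_atom_names(code_right)])

    def contact_minima(rho_l, rho_r, shift):
        ang = _attach_angle(shift)
        n_left = c1_left + 1.47 * np.array([math.cos(math.radians(ang)),
                                            math.sin(math.radians(ang)), 0.0])
        n_right = np.array([half + shift - 1.47 * math.cos(math.radians(ang)),
                            1.47 * math.sin(math.radians(ang)), 0.0])
        la = tpl_l @ _rot_z(ang + rho_l).T + n_left
        ra = tpl_r @ (_rot_z(180.0 - ang - rho_r) @ _FLIP_X).T + n_right
        d = np.linalg.norm(la[:, None, :] - ra[None, :, :], axis=-1)
        polar = d[np.ix_(polar_left, polar_right)]
        return float(d.min()), float(polar.min()), int((polar < PAIR_HBOND_CEILING).sum())

    # feasibility: every heavy-atom contact above the clash floor, yet
    # polar-polar (hydrogen-bond-like) contacts inside the detection
    # ceiling.  Prefer many such contacts (detection stays robust under
    # coordinate noise), then the smallest slide, then clearance.
    best = None
    for shift in np.arange(0.0, 1.11, 0.1):
        for rho_l in np.arange(-24.0, 24.1, 2.0):
            for rho_r in np.arange(-24.0, 24.1, 2.0):
                any_min, polar_min, n_close = contact_minima(rho_l, rho_r, shift)
                if any_min >= PAIR_CONTACT_TARGET and polar_min <= PAIR_HBOND_CEILING:
                    key = (-min(n_close, 4), round(shift, 6), -any_min,
                           abs(rho_l) + abs(rho_r))
                    if best is None or key < best[0]:
                        best = (key, rho_l, rho_r, shift)
        if best is not None and -best[0][0] >= 4:
            break  # enough contacts; larger slides cannot beat this key
    if best is None:
        raise RuntimeError(f"no feasible pair geometry for {code_left}")
    _, rho_l, rho_r, shift = best
    return (*build(rho_l, rho_r, shift), code_right)


_PAIR_CACHE: dict[str, tuple] = {}


def _pair_atoms(code_left: str):
    if code_left not in _PAIR_CACHE:
        _PAIR_CACHE[code_left] = _pair_geometry(code_left)
    return _PAIR_CACHE[code_left]


#: helix axis position in pair-frame coordinates, chosen to maximize the
#: worst-case geometric margin of the stack detector over all pair-family
#: combinations and the supported twist/rise ranges: sequence-adjacent
#: intra-strand bases always stack, cross-strand neighbours never do
_AXIS_POINT = np.array([-1.2, 1.6, 0.0])


def _axis_transform() -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform putting the helix axis (through z) at the origin."""
    return np.eye(3), -_AXIS_POINT


# ---------------------------------------------------------------------------
# rigid idealized ribose-phosphate unit


def _sugar_unit() -> dict[str, np.ndarray]:
    """Idealized ribose + phosphate arm, C1' at the origin, C1'->N along +x."""
    r = 1.46 / (2.0 * math.sin(math.pi / 5.0))
    ring_angles = {"C1'": 90.0, "C2'": 18.0, "C3'": -54.0, "C4'": -126.0, "O4'": 162.0}
    unit = {name: np.array([r * math.cos(math.radians(a)),
                            r * math.sin(math.radians(a)), 0.0])
            for name, a in ring_angles.items()}
    unit["C3'"] = unit["C3'"] + np.array([0.0, 0.0, 0.45])  # C3'-endo-ish pucker

    def _out(atom, extra, length):
        p = unit[atom]
        d = np.array([p[0], p[1], 0.0])
        d = d / np.linalg.norm(d)
        v = d + np.asarray(extra, dtype=float)
        return p + length * v / np.linalg.norm(v)

    unit["O2'"] = _out("C2'", (0.0, 0.0, -1.2), 1.41)
    unit["O3'"] = _out("C3'", (0.0, 0.0, 0.9), 1.43)
    unit["C5'"] = _out("C4'", (0.0, 0.0, 1.1), 1.51)
    d5 = unit["C5'"] - unit["C4'"]
    d5 = d5 / np.linalg.norm(d5)
    unit["O5'"] = unit["C5'"] + 1.44 * (0.75 * d5 + np.array([0.0, 0.0, 0.66]))
    dp = unit["O5'"] - unit["C5'"]
    dp = dp / np.linalg.norm(dp)
    unit["P"] = unit["O5'"] + 1.59 * (0.8 * dp + np.array([0.0, -0.6, 0.0]))
    # terminal phosphate oxygens, roughly tetrahedral about P
    po = unit["P"] - unit["O5'"]
    po = po / np.linalg.norm(po)
    perp = np.cross(po, [0.0, 0.0, 1.0])
    perp = perp / np.linalg.norm(perp)
    perp2 = np.cross(po, perp)
    unit["OP1"] = unit["P"] + 1.48 * (0.55 * po + 0.835 * perp)
    unit["OP2"] = unit["P"] + 1.48 * (0.55 * po - 0.835 * perp2)

    # move C1' to origin and align the glycosidic direction with +x
    c1 = unit["C1'"].copy()
    unit = {k: v - c1 for k, v in unit.items()}
    n_dir = np.array([0.0, 1.37, -0.53])
    n_dir = n_dir / np.linalg.norm(n_dir)
    x = n_dir
    z = np.cross(x, [0.0, 0.0, 1.0])
    z = np.cross(x, z)
    z = z / np.linalg.norm(z)
    y = np.cross(z, x)
    basis = np.array([x, y, z])  # rows: new axes expressed in old frame
    return {k: basis @ v for k, v in unit.items()}


_SUGAR = _sugar_unit()
_SUGAR_NAMES = tuple(n for n in _SUGAR if n != "C1'")


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = math.cos(angle), math.sin(angle)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) * c + s * k + (1 - c) * np.outer(axis, axis)


def _align_x(direction: np.ndarray) -> np.ndarray:
    """A rotation sending +x onto *direction* (unit)."""
    x = np.array([1.0, 0.0, 0.0])
    d = direction / np.linalg.norm(direction)
    v = np.cross(x, d)
    c = float(np.dot(x, d))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    return _rotation_about_axis(v / np.linalg.norm(v), math.acos(max(-1.0, min(1.0, c))))


def _attach_sugars(anchors: list[tuple[np.ndarray, np.ndarray]],
                   atom_sets: list[dict[str, np.ndarray]]) -> None:
    """Attach the rigid sugar unit at every (C1', glycosidic direction) anchor.

    The free rotation about the glycosidic axis is chosen greedily 5'->3' to
    bring each residue's P next to the previous residue's O3'; afterwards
    every O3' is re-aimed along the exact C3'->P(next) direction so that the
    backbone linkage closes whenever geometrically possible.
    """
    placed: list[dict[str, np.ndarray]] = []
    prev_o3: np.ndarray | None = None
    for i, (c1, gdir) in enumerate(anchors):
        base_rot = _align_x(gdir)

        def unit_at(phi: float) -> dict[str, np.ndarray]:
            rot = _rotation_about_axis(gdir, phi) @ base_rot
            return {k: rot @ v + c1 for k, v in _SUGAR.items()}

        if prev_o3 is None:
            # 5' end: point the phosphate arm back along the chain direction
            nxt = anchors[i + 1][0] if len(anchors) > 1 else c1 + gdir
            target = c1 - 2.5 * (nxt - c1) / np.linalg.norm(nxt - c1)
        else:
            target = prev_o3
        best_phi, best_d = 0.0, float("inf")
        for phi in np.linspace(0.0, 2.0 * math.pi, 73):
            # aim for a bonded O3'-P separation, not coincidence
            d = abs(float(np.linalg.norm(unit_at(phi)["P"] - target)) - 1.59)
            if d < best_d:
                best_phi, best_d = phi, d
        unit = unit_at(best_phi)
        placed.append(unit)
        prev_o3 = unit["O3'"]

    # close the O3'(i) - P(i+1) linkage where reachable: aim O3' along the
    # C3' -> P(next) direction, tilted a little off-axis so the epsilon and
    # zeta torsions around the linkage stay non-degenerate
    for i in range(len(placed) - 1):
        c3 = placed[i]["C3'"]
        p_next = placed[i + 1]["P"]
        gap = p_next - c3
        norm = float(np.linalg.norm(gap))
        if 1.5 < norm < 3.9:
            axis = gap / norm
            side = placed[i]["C2'"] - c3
            perp = np.cross(axis, side)
            perp = perp / np.linalg.norm(perp)
            direction = axis + 0.25 * perp
            placed[i]["O3'"] = c3 + 1.43 * direction / np.linalg.norm(direction)
    for i, unit in enumerate(placed):
        for name in _SUGAR_NAMES:
            atom_sets[i][name] = unit[name]
        atom_sets[i]["C1'"] = unit["C1'"]


# ---------------------------------------------------------------------------
# fixtures


@dataclass
class GroundTruth:
    """Declared interactions of a generated fixture.

    Edge keys are ``((chain_id, residue_label), (chain_id, residue_label))``
    with the two endpoints sorted.
    """

    pairs: set = field(default_factory=set)
    stacks: set = field(default_factory=set)


@dataclass
class FixtureSpec:
    """Recipe for one synthetic structure."""

    topology: str = "duplex"           # single | duplex | hairpin
    length: int = 6                    # nucleotides per strand (duplex) / total
    sequence: str | None = None        # strand-1 sequence; random if None
    noise_sigma: float = 0.0           # iid Gaussian coordinate noise, Å
    seed: int = 0
    twist: float = DEFAULT_TWIST       # helical twist per step, degrees
    rise: float = DEFAULT_RISE         # helical rise per step, Å


def _edge(a, b):
    return tuple(sorted((a, b)))


def _random_sequence(rng, n):
    return "".join(rng.choice(list("AUCG")) for _ in range(n))


def _helix_op(i: int, twist: float, rise: float):
    rot = _rot_z(-i * twist)
    shift = np.array([0.0, 0.0, i * rise])
    return rot, shift


def _pair_slot(code1: str, i: int, twist: float, rise: float):
    """Global base coordinates for helix slot *i*: (left atoms, right atoms).

    *code1* is the strand-1 residue; the right-hand coordinates belong to its
    complement on the antiparallel strand.
    """
    axis_rot, axis_shift = _axis_transform()
    hrot, hshift = _helix_op(i, twist, rise)
    left, right, right_code = _pair_atoms(code1)
    left_code = code1

    def _tx(atoms):
        return {k: hrot @ (axis_rot @ v + axis_shift) + hshift for k, v in atoms.items()}

    return _tx(left), _tx(right), left_code, right_code


def _build_structure(chains_spec, noise_sigma, rng, source_id) -> Structure:
    """chains_spec: list of (chain_id, [(code, atoms_dict), ...])."""
    structure = Structure(source_id=source_id)
    for chain_id, residues in chains_spec:
        chain = Chain(chain_id=chain_id)
        for k, (code, atom_map) in enumerate(residues):
            res = Residue(code=code, seq_index=k + 1, label=str(k + 1))
            for name, xyz in atom_map.items():
                coords = np.asarray(xyz, dtype=float)
                if noise_sigma > 0:
                    coords = coords + rng.normal(0.0, noise_sigma, 3)
                res.atoms[name] = Atom(name=name, coords=coords)
            chain.residues.append(res)
        structure.chains.append(chain)
    flag_chain_breaks(structure)
    return structure


def make_fixture(spec: FixtureSpec) -> tuple[Structure, GroundTruth]:
    """Build one synthetic structure plus its declared interaction network."""
    rng = np.random.default_rng(spec.seed)
    if spec.length < 1:
        raise ValueError("length must be >= 1")
    if spec.topology not in ("single", "duplex", "hairpin"):
        raise ValueError(f"unsupported topology {spec.topology!r}")

    if spec.topology == "hairpin":
        if spec.length < 8 or (spec.length - 4) % 2:
            raise ValueError("hairpin needs length >= 8 with an even stem")
        return _make_hairpin(spec, rng)

    seq = spec.sequence or _random_sequence(rng, spec.length)
    if len(seq) != spec.length or any(c not in "AUCG" for c in seq):
        raise ValueError(f"invalid sequence {seq!r}")

    truth = GroundTruth()
    left_res, right_res = [], []
    anchors_left, anchors_right = [], []
    for i, code in enumerate(seq):
        left, right, lcode, rcode = _pair_slot(code, i, spec.twist, spec.rise)
        l_c1, r_c1 = left.pop("C1'"), right.pop("C1'")
        l_n = left[GLYCOSIDIC_N[lcode]]
        r_n = right[GLYCOSIDIC_N[rcode]]
        left["C1'"] = l_c1
        right["C1'"] = r_c1
        left_res.append((lcode, left))
        right_res.append((rcode, right))
        anchors_left.append((l_c1, (l_n - l_c1) / np.linalg.norm(l_n - l_c1)))
        anchors_right.append((r_c1, (r_n - r_c1) / np.linalg.norm(r_n - r_c1)))

    n = spec.length
    _attach_sugars(anchors_left, [a for _, a in left_res])
    if spec.topology == "duplex":
        # antiparallel partner strand: 5'->3' runs down the helix
        right_res.reverse()
        anchors_right.reverse()
        _attach_sugars(anchors_right, [a for _, a in right_res])
        chains = [("A", left_res), ("B", right_res)]
        for i in range(n):
            truth.pairs.add(_edge(("A", str(i + 1)), ("B", str(n - i))))
        for cid, m in (("A", n), ("B", n)):
            for i in range(m - 1):
                truth.stacks.add(_edge((cid, str(i + 1)), (cid, str(i + 2))))
    else:
        chains = [("A", left_res)]
        for i in range(n - 1):
            truth.stacks.add(_edge(("A", str(i + 1)), ("A", str(i + 2))))

    structure = _build_structure(chains, spec.noise_sigma, rng,
                                 f"{spec.topology}-{seq}-s{spec.seed}")
    return structure, truth


def _make_hairpin(spec: FixtureSpec, rng) -> tuple[Structure, GroundTruth]:
    stem = (spec.length - 4) // 2
    loop = 4
    if spec.sequence:
        seq = spec.sequence
        if len(seq) != spec.length or any(c not in "AUCG" for c in seq):
            raise ValueError(f"invalid sequence {seq!r}")
        for i in range(stem):
            if COMPLEMENT[seq[i]] != seq[spec.length - 1 - i]:
                raise ValueError("hairpin stem positions must be complementary")
    else:
        stem_seq = _random_sequence(rng, stem)
        loop_seq = _random_sequence(rng, loop)
        seq = stem_seq + loop_seq + "".join(COMPLEMENT[c] for c in reversed(stem_seq))

    residues: list[tuple[str, dict]] = [None] * spec.length  # type: ignore
    anchors: list[tuple[np.ndarray, np.ndarray]] = [None] * spec.length  # type: ignore

    def record(idx, code, atoms):
        c1 = atoms["C1'"]
        n = atoms[GLYCOSIDIC_N[code]]
        residues[idx] = (code, atoms)
        anchors[idx] = (c1, (n - c1) / np.linalg.norm(n - c1))

    for i in range(stem):
        left, right, lcode, rcode = _pair_slot(seq[i], i, spec.twist, spec.rise)
        record(i, lcode, left)
        record(spec.length - 1 - i, rcode, right)

    # loop residues continue the 5'-side helical track upward: they keep
    # stacking on the 5' stem (declared below) and stay clear of the 3'
    # stem, whose pairing partners stop at the stem top.  The chain is
    # covalently broken at the loop-to-3'-stem junction, which only makes
    # the torsions spanning it undefined.
    for k in range(loop):
        left, _, lcode, _ = _pair_slot(seq[stem + k], stem + k, spec.twist, spec.rise)
        record(stem + k, lcode, left)

    # 5' arm (stem + loop) and 3' arm are each contiguous anchor tracks
    five_prime = spec.length - stem
    _attach_sugars(anchors[:five_prime], [a for _, a in residues[:five_prime]])
    _attach_sugars(anchors[five_prime:], [a for _, a in residues[five_prime:]])
    truth = GroundTruth()
    for i in range(stem):
        truth.pairs.add(_edge(("A", str(i + 1)), ("A", str(spec.length - i))))
    for i in range(five_prime - 1):
        truth.stacks.add(_edge(("A", str(i + 1)), ("A", str(i + 2))))
    for i in range(five_prime, spec.length - 1):
        truth.stacks.add(_edge(("A", str(i + 1)), ("A", str(i + 2))))
    structure = _build_structure([("A", residues)], spec.noise_sigma, rng,
                                 f"hairpin-{seq}-s{spec.seed}")
    return structure, truth


# ---------------------------------------------------------------------------
# decoys and corpora


def make_decoys(reference: Structure, n: int, sigma_ramp, seed: int = 0,
                ) -> list[tuple[Structure, float]]:
    """Perturbation decoys: iid Gaussian coordinate noise per model.

    The *n* models are split evenly over the ramp of noise levels, so the
    RMSD-to-reference spread grows along the ensemble.  Returns
    ``(structure, sigma_used)`` tuples; RMSDs of interest are computed by the
    caller against *reference*.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sigma_ramp = list(sigma_ramp)
    if not sigma_ramp or any(s < 0 for s in sigma_ramp):
        raise ValueError("sigma_ramp must be non-empty, all values >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        sigma = sigma_ramp[k * len(sigma_ramp) // n]
        decoy = Structure(source_id=f"{reference.source_id}-decoy{k}",
                          model_index=reference.model_index)
        for chain in reference.chains:
            new_chain = Chain(chain_id=chain.chain_id)
            for res in chain.residues:
                new_res = Residue(code=res.code, seq_index=res.seq_index, label=res.label)
                for name, atom in res.atoms.items():
                    coords = atom.coords + rng.normal(0.0, sigma, 3) if sigma > 0 \
                        else atom.coords.copy()
                    new_res.atoms[name] = Atom(name=name, coords=coords)
                new_chain.residues.append(new_res)
            decoy.chains.append(new_chain)
        flag_chain_breaks(decoy)
        out.append((decoy, float(sigma)))
    return out


def make_training_corpus(n_structures: int, seed: int = 0,
                         noise_sigma: float = 0.05) -> list[Structure]:
    """A seeded mixture of duplexes and hairpins for training a potential.

    Helical twist and rise are jittered per structure (29-35 degrees,
    3.1-3.5 Å) to emulate conformational diversity; within-pair contact
    geometry, which carries the base-pairing signal, is unaffected by the
    jitter.  Sequences are random, so common pair types accumulate counts
    quickly as *n_structures* grows.
    """
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    rng = np.random.default_rng(seed)
    corpus = []
    for k in range(n_structures):
        topology = "duplex" if k % 3 else "hairpin"
        length = 12 if topology == "hairpin" else int(rng.integers(6, 11))
        spec = FixtureSpec(
            topology=topology, length=length, sequence=None,
            noise_sigma=noise_sigma, seed=int(rng.integers(0, 2**31 - 1)),
            twist=float(rng.uniform(29.0, 35.0)), rise=float(rng.uniform(3.1, 3.5)))
        structure, _ = make_fixture(spec)
        corpus.append(structure)
    return corpus


def decoy_rmsds(reference: Structure, decoys) -> list[float]:
    """Convenience: all-heavy-atom RMSD of each decoy to the reference."""
    return [structure_rmsd(reference, d) for d, _ in decoys]
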