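"""Geometric detection of base-pairing and base-stacking contacts.

Base pairing and base stacking are the two interaction classes that make
up an RNA's interaction network, the object compared by the interaction
network fidelity (INF) metric.  This module is a self-contained geometric
annotator: pairing is recognized from C1'-C1' separation, a close
donor/acceptor heavy-atom contact and near-coplanar base planes; stacking
from parallel base planes at a vertical, van-der-Waals offset.  All
thresholds are configuration keys; an externally produced annotation can
be imported instead (:func:`read_interaction_set`) when a reference
annotator is preferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .atom_types import BASE_ATOMS
from .structure_io import Structure

log = logging.getLogger(__name__)

#: base ring atoms used to fit the base plane
_RING_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
}


@dataclass
class AnnotationConfig:
    """Geometric thresholds for the two detectors (Å and degrees)."""

    pair_c1_min: float = 8.0        # C1'-C1' window; relaxed to 4 Å in
    pair_c1_max: float = 12.0       # non-canonical mode
    pair_hbond_max: float = 3.5     # closest donor-acceptor heavy-atom pair
    pair_normal_max_deg: float = 65.0
    pair_plane_sep_max: float = 2.5  # vertical separation of base planes
    stack_centroid_max: float = 5.5
    stack_normal_max_deg: float = 30.0
    stack_offset_min: float = 2.5   # centroid offset along the mean normal
    stack_offset_max: float = 5.5
    non_canonical: bool = False

    @property
    def c1_min(self) -> float:
        return 4.0 if self.non_canonical else self.pair_c1_min


@dataclass
class InteractionSet:
    """Labeled edge sets over residues, keyed by (chain id, residue label)."""

    pairs: set = field(default_factory=set)
    stacks: set = field(default_factory=set)

    def edges(self) -> set:
        """The labeled edge universe: ('pair'|'stack', key_a, key_b)."""
        return ({("pair", *e) for e in self.pairs}
                | {("stack", *e) for e in self.stacks})

    def __len__(self) -> int:
        return len(self.pairs) + len(self.stacks)


def _edge(a, b):
    return tuple(sorted((a, b)))


class _BaseFrame:
    """Fitted plane and donor/acceptor atoms of one base."""

    __slots__ = ("key", "centroid", "normal", "polar", "c1")

    def __init__(self, key, centroid, normal, polar, c1):
        self.key = key
        self.centroid = centroid
        self.normal = normal
        self.polar = polar
        self.c1 = c1


def _base_frames(structure: Structure) -> list[_BaseFrame]:
    frames = []
    for chain in structure.chains:
        for res in chain.residues:
            ring = [res.coord(n) for n in _RING_ATOMS[res.code]]
            ring = [p for p in ring if p is not None]
            if len(ring) < 3:
                log.warning("residue %s/%s lacks ring atoms; skipped in annotation",
                            chain.chain_id, res.label)
                continue
            ring = np.array(ring)
            centroid = ring.mean(axis=0)
            # plane normal: smallest-variance direction of the ring atoms
            _, s, vt = np.linalg.svd(ring - centroid)
            if s[1] < 1e-6:  # degenerate (collinear) base
                log.warning("degenerate base plane at %s/%s; skipped",
                            chain.chain_id, res.label)
                continue
            normal = vt[2]
            polar = np.array([res.coord(n) for n in BASE_ATOMS[res.code]
                              if n.startswith(("N", "O")) and res.coord(n) is not None])
            frames.append(_BaseFrame((chain.chain_id, res.label), centroid,
                                     normal, polar, res.coord("C1'")))
    return frames


def _normal_angle_deg(n1, n2) -> float:
    """Angle between undirected plane normals, in [0, 90]."""
    c = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(min(1.0, c))))


def detect_base_pairs(structure: Structure,
                      config: AnnotationConfig | None = None) -> set:
    """Residue pairs joined by a (canonical or near-canonical) base pair."""
    config = config or AnnotationConfig()
    frames = _base_frames(structure)
    edges = set()
    for i in range(len(frames)):
        for j in range(i + 1, len(frames)):
            a, b = frames[i], frames[j]
            if a.c1 is None or b.c1 is None:
                continue
            d_c1 = float(np.linalg.norm(a.c1 - b.c1))
            if not (config.c1_min <= d_c1 <= config.pair_c1_max):
                continue
            if _normal_angle_deg(a.normal, b.normal) > config.pair_normal_max_deg:
                continue
            # vertical separation of the two base planes
            delta = b.centroid - a.centroid
            sep = max(abs(float(np.dot(delta, a.normal))),
                      abs(float(np.dot(delta, b.normal))))
            if sep > config.pair_plane_sep_max:
                continue
            if a.polar.size == 0 or b.polar.size == 0:
                continue
            dmin = np.linalg.norm(a.polar[:, None, :] - b.polar[None, :, :],
                                  axis=-1).min()
            if dmin < config.pair_hbond_max:
                edges.add(_edge(a.key, b.key))
    return edges


def detect_stacking(structure: Structure,
                    config: AnnotationConfig | None = None) -> set:
    """Residue pairs whose bases stack (parallel planes, vertical offset)."""
    config = config or AnnotationConfig()
    frames = _base_frames(structure)
    edges = set()
    for i in range(len(frames)):
        for j in range(i + 1, len(frames)):
            a, b = frames[i], frames[j]
            delta = b.centroid - a.centroid
            if float(np.linalg.norm(delta)) > config.stack_centroid_max:
                continue
            if _normal_angle_deg(a.normal, b.normal) > config.stack_normal_max_deg:
                continue
            n2 = b.normal if np.dot(a.normal, b.normal) >= 0 else -b.normal
            mean_normal = a.normal + n2
            mean_normal = mean_normal / np.linalg.norm(mean_normal)
            offset = abs(float(np.dot(delta, mean_normal)))
            if config.stack_offset_min <= offset <= config.stack_offset_max:
                edges.add(_edge(a.key, b.key))
    return edges


def annotate(structure: Structure,
             config: AnnotationConfig | None = None) -> InteractionSet:
    """Full interaction network: base pairs plus base stacks."""
    config = config or AnnotationConfig()
    return InteractionSet(pairs=detect_base_pairs(structure, config),
                          stacks=detect_stacking(structure, config))


def interaction_set_from_truth(truth) -> InteractionSet:
    """Wrap a generator ground truth (or anything with .pairs/.stacks)."""
    return InteractionSet(pairs=set(truth.pairs), stacks=set(truth.stacks))


def read_interaction_set(path) -> InteractionSet:
    """Import an externally produced annotation.

    Format: one edge per line, ``label chain:res chain:res`` with label
    ``pair`` or ``stack``; lines starting with ``#`` are ignored.
    """
    result = InteractionSet()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, a, b = line.split()
            key_a = tuple(a.split(":", 1))
            key_b = tuple(b.split(":", 1))
            if label == "pair":
                result.pairs.add(_edge(key_a, key_b))
            elif label == "stack":
                result.stacks.add(_edge(key_a, key_b))
            else:
                raise ValueError(f"unknown interaction label {label!r}")
    return result


def write_interaction_set(interactions: InteractionSet, path) -> None:
    with open(path, "w") as fh:
        for label, edges in (("pair", interactions.pairs),
                             ("stack", interactions.stacks)):
            for a, b in sorted(edges):
                fh.write(f"{label} {a[0]}:{a[1]} {b[0]}:{b[1]}\n")
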