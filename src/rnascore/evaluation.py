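"""Decoy-set protocols: native identification, ranking, weight
optimization and INF-based clustering with representative selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .annotation import AnnotationConfig, annotate
from .metrics import compare_structures, deformation_index, enrichment_score, inf_score
from .potential import PotentialModel
from .scoring import ScoreResult, score_total
from .structure_io import Structure

log = logging.getLogger(__name__)


@dataclass
class DecoyRecord:
    """One model of a decoy ensemble with its score and quality metrics."""

    id: str
    score: ScoreResult
    rmsd: float = float("nan")
    inf: float = float("nan")
    di: float = float("nan")


def evaluate_decoys(reference: Structure, decoys, model: PotentialModel,
                    native_id: str = "native",
                    config: AnnotationConfig | None = None) -> list[DecoyRecord]:
    """Score the reference plus decoys and measure each against the reference.

    Returns one record per structure, the reference first under *native_id*.
    """
    ref_interactions = annotate(reference, config)
    records = [DecoyRecord(id=native_id, score=score_total(reference, model),
                           rmsd=0.0, inf=1.0, di=0.0)]
    for k, decoy in enumerate(decoys):
        cmp = compare_structures(reference, decoy, config,
                                 ref_interactions=ref_interactions)
        records.append(DecoyRecord(
            id=decoy.source_id or f"decoy{k}", score=score_total(decoy, model),
            rmsd=cmp.rmsd, inf=cmp.inf, di=cmp.di))
    return records


def identify_native(records: list[DecoyRecord],
                    native_id: str) -> tuple[bool, int]:
    """Whether the native has strictly the lowest energy, plus its rank.

    The rank is the 1-based position after a stable ascending sort on total
    energy.  A tie at the minimum counts as a failure to identify.
    """
    ids = [r.id for r in records]
    if native_id not in ids:
        raise ValueError(f"native id {native_id!r} not among records")
    energies = np.array([r.score.total for r in records])
    order = np.argsort(energies, kind="stable")
    rank = int(np.flatnonzero(np.array(ids)[order] == native_id)[0]) + 1
    native_energy = energies[ids.index(native_id)]
    identified = bool((energies < native_energy).sum() == 0
                      and (energies == native_energy).sum() == 1)
    return identified, rank


def ranking_table(records: list[DecoyRecord], fraction: float = 0.1,
                  quality: str = "di") -> dict:
    """Summary of a scored ensemble: per-decoy rows plus native rank and ES."""
    energies = [r.score.total for r in records]
    qualities = [getattr(r, quality) for r in records]
    es = enrichment_score(energies, qualities, fraction)
    return {"records": records, "enrichment_score": es, "quality": quality}


@dataclass
class ScoredEnsemble:
    """Inputs to weight optimization: per-model terms plus DI values."""

    distance_terms: np.ndarray
    dihedral_terms: np.ndarray
    di: np.ndarray

    @classmethod
    def from_records(cls, records: list[DecoyRecord]) -> "ScoredEnsemble":
        return cls(
            distance_terms=np.array([r.score.distance_term for r in records]),
            dihedral_terms=np.array([r.score.dihedral_term for r in records]),
            di=np.array([r.di for r in records]))


def optimize_weight(ensembles: list[ScoredEnsemble], weight_init: float = 1.0,
                    fraction: float = 0.1, grid_max: float = 20.0,
                    grid_points: int = 201, refine_tol: float = 1e-3) -> float:
    """Weight of the torsion term maximizing the mean DI enrichment score.

    The objective omega -> mean ES over ensembles is piecewise constant
    (the ES changes only when two models swap rank), so a derivative-free
    search is used: a coarse grid over [0, grid_max] followed by
    golden-section refinement around the best grid point.  Deterministic
    for fixed inputs.
    """
    for ens in ensembles:
        if ens.di.size < 20:
            raise ValueError("each ensemble needs at least 20 members")
        if not (np.isfinite(ens.distance_terms).all()
                and np.isfinite(ens.dihedral_terms).all()
                and np.isfinite(ens.di).all()):
            raise ValueError("ensemble terms and DI must be finite")

    def objective(w: float) -> float:
        return float(np.mean([
            enrichment_score(ens.distance_terms + w * ens.dihedral_terms,
                             ens.di, fraction) for ens in ensembles]))

    grid = np.linspace(0.0, grid_max, grid_points)
    values = np.array([objective(w) for w in grid])
    if np.allclose(values, values[0]):
        log.warning("flat enrichment objective; returning initial weight")
        return float(weight_init)
    best = int(values.argmax())
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_points - 1)]
    # golden-section refinement on the bracketing interval
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc, fd = objective(c), objective(d)
    while b - a > refine_tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = objective(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = objective(d)
    candidates = [(objective(w), w) for w in (grid[best], (a + b) / 2.0)]
    return float(max(candidates)[1])


@dataclass
class ClusterGroup:
    members: list[str]
    representative: str          # lowest total energy
    center: str                  # medoid under the INF dissimilarity
    min_di: str | None = None    # lowest DI, when a reference is given

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterResult:
    groups: list[ClusterGroup] = field(default_factory=list)

    @property
    def sizes(self) -> list[int]:
        return [g.size for g in self.groups]


def cluster_by_inf(models: list[Structure], threshold: float,
                   model: PotentialModel,
                   reference: Structure | None = None,
                   config: AnnotationConfig | None = None) -> ClusterResult:
    """Complete-linkage clustering under the 1 - INF dissimilarity.

    Every within-group model pair then satisfies 1 - INF <= threshold.  Per
    group the lowest-energy member is the representative candidate; the
    medoid and (with a reference) the minimum-DI member are reported too.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to cluster")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    n = len(models)
    ids = [m.source_id or f"model{k}" for k, m in enumerate(models)]
    interactions = []
    failed = set()
    for k, m in enumerate(models):
        ann = annotate(m, config)
        if len(ann) == 0:
            failed.add(k)
            log.warning("model %s has no detectable interactions; singleton group",
                        ids[k])
        interactions.append(ann)

    dissim = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            if a in failed or b in failed:
                d = 1.0
            else:
                d = 1.0 - inf_score(interactions[a], interactions[b])
            dissim[a, b] = dissim[b, a] = d

    labels = fcluster(linkage(squareform(dissim, checks=False), method="complete"),
                      t=threshold, criterion="distance")
    energies = np.array([score_total(m, model).total for m in models])
    di = None
    if reference is not None:
        di = np.array([compare_structures(reference, m, config).di for m in models])

    groups = []
    for g in sorted(set(labels)):
        idx = np.flatnonzero(labels == g)
        sub = dissim[np.ix_(idx, idx)]
        rep = idx[int(energies[idx].argmin())]
        center = idx[int(sub.mean(axis=1).argmin())]
        group = ClusterGroup(
            members=[ids[k] for k in idx],
            representative=ids[rep], center=ids[center],
            min_di=ids[idx[int(di[idx].argmin())]] if di is not None else None)
        groups.append(group)
    groups.sort(key=lambda g: -g.size)
    return ClusterResult(groups=groups)
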