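"""Model-quality metrics: INF/MCC, deformation index, enrichment score.

INF (interaction network fidelity) compares the base-pair/stack edge sets
of two structures through the square-root Matthews approximation

    INF = sqrt(PPV * STY),  PPV = TP/(TP+FP),  STY = TP/(TP+FN),

with TP/FP/FN taken over the labeled edge universe (pairs and stacks as
distinct edges).  DI (deformation index) = RMSD / INF penalizes models
that are geometrically close but topologically wrong.  The enrichment
score measures how well an energy ranking concentrates the truly best
fraction of a decoy set:

    ES = |E_top f  ∩  R_top f| / (f^2 N),

so a perfect monotone relation at f = 0.1 gives 10, independence gives 1
in expectation, and anti-correlation gives 0.
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction
from dataclasses import dataclass

import numpy as np

from .annotation import AnnotationConfig, InteractionSet, annotate
from .errors import UndefinedReferenceError
from .geometry import structure_rmsd
from .structure_io import Structure

log = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    """Geometric + topological comparison of a model against a reference."""

    rmsd: float
    inf: float
    di: float
    tp: int
    fp: int
    fn: int


def interaction_counts(s_ref: InteractionSet,
                       s_model: InteractionSet) -> tuple[int, int, int]:
    ref, mdl = s_ref.edges(), s_model.edges()
    tp = len(ref & mdl)
    fp = len(mdl - ref)
    fn = len(ref - mdl)
    return tp, fp, fn


def inf_score(s_ref: InteractionSet, s_model: InteractionSet) -> float:
    """sqrt(PPV x sensitivity) over the labeled edge universe, in [0, 1]."""
    if len(s_ref) == 0:
        raise UndefinedReferenceError("reference interaction set is empty")
    if len(s_model) == 0:
        log.info("model interaction set empty; INF = 0 by convention")
        return 0.0
    tp, fp, fn = interaction_counts(s_ref, s_model)
    if tp == 0:
        return 0.0
    ppv = tp / (tp + fp)
    sty = tp / (tp + fn)
    return math.sqrt(ppv * sty)


def deformation_index(rmsd: float, inf: float) -> float:
    """RMSD / INF (Å); an INF of zero yields +inf so ranking still works."""
    if inf < 0 or inf > 1:
        raise ValueError("inf must lie in [0, 1]")
    if inf == 0.0:
        return math.inf
    return rmsd / inf


def compare_structures(reference: Structure, model: Structure,
                       config: AnnotationConfig | None = None,
                       ref_interactions: InteractionSet | None = None,
                       ) -> ComparisonResult:
    """All-heavy-atom RMSD, INF and DI of *model* against *reference*."""
    rmsd = structure_rmsd(reference, model)
    s_ref = ref_interactions or annotate(reference, config)
    s_model = annotate(model, config)
    tp, fp, fn = interaction_counts(s_ref, s_model)
    inf = inf_score(s_ref, s_model)
    return ComparisonResult(rmsd=rmsd, inf=inf,
                            di=deformation_index(rmsd, inf),
                            tp=tp, fp=fp, fn=fn)


def _top_fraction_indices(values: np.ndarray, k: int) -> set:
    """Indices of the k smallest values; ties broken by input order."""
    order = np.argsort(values, kind="stable")
    return set(int(x) for x in order[:k])


def enrichment_score(energies, quality, fraction: float = 0.1,
                     range_based: bool = False) -> float:
    """Overlap of the best-scored and truly-best fractions of a decoy set.

    *energies* and *quality* are parallel sequences (lower is better for
    both; quality is typically RMSD or DI).  The top sets are rank-based by
    default: the ``floor(fraction*N)`` lowest values, stable under ties.
    ``range_based`` instead takes values within the lowest *fraction* of
    each quantity's value range (the literal reading; under it the perfect
    score is not exactly 1/fraction).
    """
    e = np.asarray(energies, dtype=float)
    q = np.asarray(quality, dtype=float)
    if e.shape != q.shape or e.ndim != 1:
        raise ValueError("energies and quality must be equal-length 1-D sequences")
    n = e.size
    if not (0.0 < fraction <= 0.5):
        raise ValueError("fraction must lie in (0, 0.5]")
    k = int(n * fraction)
    if k < 1:
        raise ValueError("fraction * N must be at least 1")
    if range_based:
        e_set = set(np.flatnonzero(e <= e.min() + fraction * (e.max() - e.min())))
        r_set = set(np.flatnonzero(q <= q.min() + fraction * (q.max() - q.min())))
    else:
        e_set = _top_fraction_indices(e, k)
        r_set = _top_fraction_indices(q, k)
    # rational denominator so that a perfect ranking at fraction 0.1 is
    # exactly 10, matching the analytic bound
    denom = Fraction(str(fraction)) ** 2 * n
    return float(Fraction(len(e_set & r_set)) / denom)
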