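# Methods

## Model

The scoring function is a potential of mean force obtained by inverse
Boltzmann statistics on a corpus of RNA structures. It rests on three
assumptions standard for knowledge-based potentials: the total relative
free energy decomposes into a sum over individual reaction coordinates;
each contribution follows from the inverse of Boltzmann's law against a
reference state; and the native conformation occupies the free-energy
minimum, so lower scores should mean more native-like models.

Two reaction coordinates are used.

**Inter-atomic distances.** All 85 heavy-atom types of A, U, C, G are
distinguished (12 shared sugar-phosphate types per residue plus 10/8/8/11
base types). For each unordered type pair, distances between atoms in
different residues are histogrammed below a 20 Å cutoff and normalized by
the *averaged* reference state, i.e. the pooled distance distribution of
all type pairs. This reference requires no covalent-bond modelling and is
usable with modest corpora. Sequence-adjacent residues of a chain are
excluded from counting except their base–base atom pairs: adjacent
backbones are covalently constrained (their distances carry no non-bonded
signal), but adjacent bases interact through stacking, which is exactly
the signal an RNA potential must capture. Scoring admits the identical
pair set through a shared code path, so trained and scored ensembles
match.

**Torsion angles.** The six backbone torsions α–ζ (IUPAC atom
quadruples) and the glycosidic angle χ (O4′–C1′–N9–C4 for purines,
O4′–C1′–N1–C2 for pyrimidines), each on [0°, 360°) with 0° = cis. The
seven angle types form seven histogram rows inverted against their
pooled reference. A joint formulation over consecutive-angle pairs was
considered and rejected: no defining formula exists for it, and the
single-angle construction is the one the energy equations support.

The two terms combine as `E_total = E_distance + ω·E_dihedral` with the
shipped default ω = 3.68. `optimize_weight` re-derives ω for any decoy
collections by maximizing the mean DI-based enrichment score; because
the objective is piecewise constant in ω (it changes only at rank
crossings), the optimizer is derivative-free — a 201-point grid on
[0, 20] followed by golden-section refinement — rather than a gradient
method, and is deterministic.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| distance bin width Δd | 0.3 | Å | Scott's rule W = 3.49σN^(−1/3) at corpus scale; configurable |
| cutoff | 20 | Å | beyond it pair frequencies carry no structural signal |
| torsion bin width Δθ | 4.5 | ° | Scott's rule; gives 80 bins over the circle |
| clash floor | 3 | Å | sub-3 Å distances are too sparse to train; physically the excluded-volume region |
| clash penalty | +10 | k_BT | bounded substitute for the untrainable region; per atom pair |
| E_max (empty bins) | +5 | k_BT | keeps scores finite and comparable across models |
| temperature T | 298 | K | recorded only; energies are in k_BT units and only relative values matter for ranking |
| ω | 3.68 | – | shipped default weight of the torsion term |
| chain-break threshold | 2.5 | Å | O3′–P ceiling for a covalent linkage; affects torsion extraction only |

Sippl's sparse-data shrinkage `g = f_pool/(1+mσ) + f_row·mσ/(1+mσ)`
(σ = 1/50 by default) is implemented but off by default: at the corpus
sizes the binning is designed for, average bin occupancy is large enough
(about 1090 samples per cell for a 5×10⁸-pair corpus under the default
binning) that shrinkage is unnecessary.

## Structure input

PDB parsing is delegated to Biopython and wrapped with scoring-specific
policies: v2/v3 atom-name dialects (`O5*`/`O1P` vs `O5'`/`OP1`) are
normalized to one spelling; hydrogens are dropped; altlocs resolve to
the highest-occupancy copy with file-order tie-breaking; modified or
non-RNA residues and atoms outside the 85-type table are skipped with a
warning (no MODRES remapping — only the four standard residues are
trained); multi-model files default to model 1. The atom-type numbering
convention is versioned and written into every parameter file so tables
trained under different conventions cannot be mixed silently.

## Interaction annotation

INF needs base-pair and base-stack edge sets. The annotator here is
self-contained and geometric: a pair requires a C1′–C1′ separation of
8–12 Å (4–12 Å in non-canonical mode), at least one N/O–N/O contact
below 3.5 Å, base-plane normals within 65°, and plane separation below
2.5 Å; a stack requires base centroids within 5.5 Å, normals within 30°,
and a centroid offset along the mean normal of 2.5–5.5 Å. All thresholds
are configuration keys. This is a deliberate stand-in for external
reference annotators; INF values on real structures will differ from
those produced by such tools, and externally produced edge lists can be
imported instead. The clustering protocol groups models by
complete-linkage agglomeration on the 1 − INF dissimilarity; complete
linkage is chosen so that *every* within-group pair meets the threshold
(default 0.18), the strongest guarantee a single cut can give. Per group
the lowest-energy member is the representative; the medoid and, given a
reference, the minimum-DI member are reported alongside.

The enrichment score reads "top 10%" as rank-based (the ⌊0.1N⌋ lowest
values, ties stable in input order): only under the rank reading do the
analytic bounds hold (perfect = 10, random = 1 in expectation at
fraction 0.1, computed with a rational denominator so the bound is
exact). A value-range variant is available behind a flag. Native
identification is strict: a tie at the minimum energy counts as a
failure. A deformation index with INF = 0 is reported as +inf — a
sortable sentinel, not an exception — so ranking protocols keep working.

## Synthetic data

The generator emulates just enough of RNA structure for the potential's
statistics to be meaningful: exactly the canonical heavy-atom set per
residue, planar idealized base rings, Watson–Crick-style coplanar pairs
built on a glycosidic-anchor construction (C1′–C1′ ≈ 10.5 Å, 54.5°
glycosidic angles), A-form-like helical stacking (defaults: twist 32.7°,
rise 3.2 Å), and a rigid idealized ribose-phosphate unit whose rotation
about the glycosidic axis is solved per residue to close the O3′–P
linkage. The A–U pair family pins its glycosidic N9–N1 separation at
8.79 Å — the signature distance of the pairing contact — which training
recovers as the minimum of that pair type's energy row; the G–C family,
whose bulkier exocyclic rim cannot close to that separation with
idealized rings, slides slightly wider. The helix axis position and the
in-plane base rotations were fixed once by maximizing the worst-case
geometric margins of the annotation thresholds over all pair families
and the supported twist/rise ranges, so that at zero noise the detected
network equals the declared one exactly, with no false positives.

Training corpora jitter twist (29–35°) and rise (3.1–3.5 Å) per
structure and add 0.05 Å coordinate noise: within-pair contact geometry
is invariant under the jitter, so pairing distances stay sharp while
all other inter-residue distances smear — the mechanism that makes the
pairing signature the dominant minimum of its energy row. Hairpin loops
continue the 5′-side helical track (with the single chain break at the
loop-to-3′-stem junction), so declared stacks remain exact; this is an
idealization, not a folded-back loop geometry. Decoys perturb every
coordinate with iid Gaussian noise split evenly over a ramp of
amplitudes, giving RMSD spreads of roughly 0–7 Å for ramps up to 4 Å.

What passing tests on this generator do **not** show: performance on
real experimental structures, whose base-pair geometries, modified
residues, loop conformations and crystallographic artefacts the
generator does not emulate; nor agreement with published INF/DI values,
which depend on external annotators. Because several designed contacts
sit close to detection thresholds (e.g. the A–U polar contacts at
3.06/3.37 Å against the 3.5 Å ceiling), unbounded iid noise carries a
small tail probability of dropping an edge; robustness tests therefore
pin seeds and noise levels (σ ≤ 0.3 Å).

## Numerical choices

Distances bin as ⌊d/Δd⌋ with the last bin absorbing the cutoff edge;
d = 3.0 Å belongs to the trained region (the penalty applies strictly
below 3 Å, i.e. to bins whose upper edge is ≤ 3 Å — 10 penalty bins of
67 at defaults). Pair rows are stored unordered (a ≤ b) and mirrored at
query time. Torsions at exactly 360° wrap to 0 by construction. The
Kabsch superposition enforces a proper rotation via the SVD determinant
correction. Parameter files print energies with 17 significant digits
(bit-exact round trips) and carry a SHA-256 checksum over the data
section; version, convention, shape and checksum are all verified on
load and no partial model is ever returned. Degenerate torsion
quadruples (collinear or coincident points) raise inside the primitive
but are treated as undefined angles by the extractor.

## Known limitations

- Trained and validated only on synthetic fixtures here; applying the
  potential to real PDB models requires a user-supplied training corpus.
- The geometric annotator approximates, but does not reproduce,
  reference interaction annotators; INF/DI values are internally
  consistent rather than literature-comparable.
- Only the four standard ribonucleotides are supported; modified
  residues are skipped, losing their contacts.
- Scores are not length-normalized (decoys of one RNA are compared);
  cross-RNA comparisons should normalize per residue via the score
  result's pair/torsion counts.
- The iid-noise decoy model produces no correlated, physically plausible
  deformations; enrichment behaviour on physics-based decoys (where the
  torsion term matters more) is demonstrated only qualitatively by the
  weight-optimization machinery.
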