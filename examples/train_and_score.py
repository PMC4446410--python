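"""Train a potential on a synthetic corpus and score a held-out structure.

The corpus is a seeded mixture of duplexes and hairpins; the held-out
duplex was never seen during training.  The printed numbers are the
weighted total energy (k_B T units), its distance and torsion components,
and the number of clashing (< 3 Å) atom pairs — a clean native structure
should score strongly negative with zero clashes.
"""

from rnascore import FixtureSpec, make_fixture, make_training_corpus, score_total, train

corpus = make_training_corpus(30, seed=7)
model = train(corpus, provenance="example corpus n=30 seed=7")

held_out, _ = make_fixture(FixtureSpec(topology="duplex", length=8, seed=99))
result = score_total(held_out, model)

print(f"structure: {held_out.source_id}")
print(f"total energy    : {result.total:10.1f} k_BT")
print(f"  distance term : {result.distance_term:10.1f} k_BT "
      f"({result.n_pairs_scored} atom pairs)")
print(f"  torsion term  : {result.dihedral_term:10.1f} k_BT "
      f"({result.n_torsions_scored} torsions, weight {model.weight})")
print(f"  clashes < 3 Å : {result.clash_count}")
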