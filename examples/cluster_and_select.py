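"""Cluster candidate models by interaction-network similarity.

Models are grouped by complete-linkage clustering under the 1 - INF
dissimilarity (threshold 0.18), so every within-group pair shares at
least 82% of its interaction network.  Each group's lowest-energy member
is its representative — the robust way to shortlist candidates for the
native structure.
"""

from rnascore import (FixtureSpec, cluster_by_inf, make_decoys, make_fixture,
                      make_training_corpus, train)

model = train(make_training_corpus(30, seed=7))
reference, _ = make_fixture(FixtureSpec("duplex", 8, seed=42))
other, _ = make_fixture(FixtureSpec("hairpin", 12, seed=8))
# two families: near-native models of the reference, and models of an
# unrelated fold (their interaction networks share no edges)
models = [d for d, _ in make_decoys(reference, 6, [0.2], seed=1)]
models += [d for d, _ in make_decoys(other, 5, [0.2], seed=2)]

result = cluster_by_inf(models, threshold=0.18, model=model,
                        reference=reference)
for g, group in enumerate(result.groups, start=1):
    print(f"group {g}: size {group.size:2d}  "
          f"representative {group.representative}  "
          f"center {group.center}  min-DI {group.min_di}")
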