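"""Decompose a hairpin's energy into per-residue-pair base interactions.

For a 12-nucleotide hairpin with secondary structure ((((....)))) the
base-pairing energies between the four closing pairs (1-12, 2-11, 3-10,
4-9) should be the lowest entries of the pairing profile, and the
stacking profile should show favourable energies along the stacked
5' arm.  Energies are in k_B T; lower is more favourable.
"""

from rnascore import FixtureSpec, make_fixture, make_training_corpus, train
from rnascore.scoring import pairing_profile, stacking_profile

model = train(make_training_corpus(30, seed=7))
hairpin, truth = make_fixture(FixtureSpec("hairpin", 12, seed=13))

print("declared pairs:", sorted(f"{a[1]}-{b[1]}" for a, b in truth.pairs))
print("\nbase-pairing energies (most favourable first):")
for label, energy in pairing_profile(hairpin, model)[:6]:
    print(f"  {label:>10s} {energy:8.1f} k_BT")

print("\nbase-stacking energies along the chain:")
for label, energy in stacking_profile(hairpin, model):
    print(f"  {label:>7s} {energy:8.1f} k_BT")
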