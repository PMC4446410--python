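"""Structure evaluation under a trained or toy potential."""

import numpy as np
import pytest

from conftest import (oracle_distance_score, random_rigid_motion,
                      random_small_fixture, toy_residue, toy_structure,
                      transform_structure)
from rnascore import FixtureSpec, make_fixture, score_total
from rnascore.atom_types import N_PAIR_TYPES, atom_type_index, pair_row
from rnascore.geometry import TORSION_NAMES
from rnascore.potential import PotentialModel
from rnascore.scoring import (residue_pair_energy, score_dihedral,
                              score_distance)


def toy_model(rng=None, weight=3.68, clash_penalty=10.0):
    """A potential with random (but finite) trained energies."""
    rng = rng or np.random.default_rng(0)
    distance = rng.normal(0, 1, (N_PAIR_TYPES, 67))
    distance[:, :10] = clash_penalty
    dihedral = rng.normal(0, 1, (7, 80))
    return PotentialModel(distance_energy=distance, dihedral_energy=dihedral,
                          weight=weight, clash_penalty=clash_penalty)


class TestScoreDistance:
    def test_single_residue_scores_zero(self):
        structure = toy_structure([("A", [toy_residue("A", {"N9": (0, 0, 0)})])])
        assert score_distance(structure, toy_model()) == (0.0, 0, 0)

    def test_clash_pair_contributes_penalty(self):
        r1 = toy_residue("A", {"N9": (0, 0, 0)}, 1)
        r2 = toy_residue("U", {"N1": (2.5, 0, 0)}, 1)
        structure = toy_structure([("A", [r1]), ("B", [r2])])
        term, clashes, n_pairs = score_distance(structure, toy_model())
        assert term == pytest.approx(10.0)
        assert clashes == 1 and n_pairs == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        structure = random_small_fixture(seed + 100)
        model = toy_model(np.random.default_rng(seed))
        term, _, _ = score_distance(structure, model)
        assert term == pytest.approx(oracle_distance_score(structure, model),
                                     abs=1e-9)

    def test_monotone_clash_response(self):
        model = toy_model()
        def at(distance):
            r1 = toy_residue("A", {"N9": (0, 0, 0)}, 1)
            r2 = toy_residue("U", {"N1": (distance, 0, 0)}, 1)
            return score_distance(toy_structure([("A", [r1]), ("B", [r2])]),
                                  model)[0]
        row = pair_row(atom_type_index("A", "N9"), atom_type_index("U", "N1"))
        expected_delta = model.clash_penalty - model.distance_energy[row,
                                                                     int(3.2 / 0.3)]
        assert at(2.8) - at(3.2) == pytest.approx(expected_delta, abs=1e-12)


class TestScoreDihedral:
    def test_no_defined_torsions_scores_zero(self):
        structure = toy_structure([
            ("A", [toy_residue("A", {"N9": (0, 0, 0)})]),
            ("B", [toy_residue("U", {"N1": (30, 0, 0)})])])
        assert score_dihedral(structure, toy_model()) == (0.0, 0)

    def test_single_gamma_lookup(self):
        structure, _ = make_fixture(FixtureSpec("single", 1, "A", seed=4))
        model = toy_model()
        from rnascore.geometry import backbone_torsions
        (_, _, ts), = backbone_torsions(structure)
        expected = sum(model.dihedral_energy[row, min(int(t / 4.5), 79)]
                       for row, name in enumerate(TORSION_NAMES)
                       if (t := getattr(ts, name)) is not None)
        term, n = score_dihedral(structure, model)
        assert term == pytest.approx(expected, abs=1e-12)
        assert n == 4  # beta, gamma, delta, chi for an isolated residue

    def test_matches_direct_scan_on_fixture(self):
        structure, _ = make_fixture(FixtureSpec("duplex", 5, seed=8))
        model = toy_model()
        from rnascore.geometry import backbone_torsions
        expected = 0.0
        count = 0
        for _, _, ts in backbone_torsions(structure):
            for row, name in enumerate(TORSION_NAMES):
                theta = getattr(ts, name)
                if theta is not None:
                    expected += model.dihedral_energy[row, min(int(theta / 4.5), 79)]
                    count += 1
        term, n = score_dihedral(structure, model)
        assert term == pytest.approx(expected, abs=1e-9)
        assert n == count


class TestScoreTotal:
    def test_weighted_combination(self):
        structure, _ = make_fixture(FixtureSpec("duplex", 5, seed=8))
        model = toy_model(weight=3.68)
        result = score_total(structure, model)
        assert result.total == pytest.approx(
            result.distance_term + 3.68 * result.dihedral_term, abs=1e-9)

    def test_omega_368_arithmetic(self):
        # distance -5, dihedral -2 at the shipped weight
        assert -5.0 + 3.68 * -2.0 == pytest.approx(-12.36)

    def test_zero_weight_reduces_to_distance_term(self):
        structure, _ = make_fixture(FixtureSpec("duplex", 5, seed=8))
        model = toy_model(weight=0.0)
        result = score_total(structure, model)
        assert result.total == result.distance_term

    def test_deterministic(self, trained_model):
        structure, _ = make_fixture(FixtureSpec("hairpin", 12, seed=6))
        r1 = score_total(structure, trained_model)
        r2 = score_total(structure, trained_model)
        assert r1 == r2

    def test_rigid_motion_invariance(self, trained_model):
        structure, _ = make_fixture(FixtureSpec("duplex", 6, seed=10))
        rng = np.random.default_rng(123)
        rot, shift = random_rigid_motion(rng)
        moved = transform_structure(structure, rot, shift)
        a = score_total(structure, trained_model)
        b = score_total(moved, trained_model)
        assert b.total == pytest.approx(a.total, abs=1e-6)
        assert b.clash_count == a.clash_count


class TestResiduePairDecomposition:
    @pytest.mark.parametrize("seed", range(4))
    def test_pair_energies_sum_to_distance_term(self, seed, trained_model):
        structure = random_small_fixture(seed + 50, max_len=7)
        sizes = [len(c.residues) for c in structure.chains]
        refs = [(ci, ri) for ci, n in enumerate(sizes) for ri in range(n)]
        total = sum(residue_pair_energy(structure, trained_model,
                                        refs[a], refs[b])
                    for a in range(len(refs)) for b in range(a + 1, len(refs)))
        term, _, _ = score_distance(structure, trained_model)
        assert total == pytest.approx(term, abs=1e-9)

    def test_same_residue_rejected(self, trained_model):
        structure = random_small_fixture(1)
        with pytest.raises(ValueError):
            residue_pair_energy(structure, trained_model, (0, 0), (0, 0))

    def test_far_apart_residues_score_zero(self, trained_model):
        r1 = toy_residue("A", {"N9": (0, 0, 0)}, 1)
        r2 = toy_residue("U", {"N1": (100, 0, 0)}, 1)
        structure = toy_structure([("A", [r1]), ("B", [r2])])
        assert residue_pair_energy(structure, trained_model, (0, 0), (1, 0)) == 0.0

    def test_paired_residues_have_lower_base_energy_than_unpaired(
            self, trained_model, duplex_fixture):
        """In a trained model, hydrogen-bonded partners should sit in an
        energy well relative to non-interacting residue pairs."""
        structure, truth = duplex_fixture
        n = len(structure.chains[0].residues)
        paired, unpaired = [], []
        for i in range(n):
            for j in range(n):
                e = residue_pair_energy(structure, trained_model,
                                        (0, i), (1, j), base_only=True)
                key = tuple(sorted([("A", str(i + 1)), ("B", str(j + 1))]))
                (paired if key in truth.pairs else unpaired).append(e)
        assert max(paired) < min(unpaired)
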