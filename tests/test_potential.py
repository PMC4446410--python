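"""Count accumulation, Boltzmann inversion and parameter-file persistence."""

import math

import numpy as np
import pytest

from conftest import (oracle_distance_counts, random_small_fixture,
                      toy_residue, toy_structure)
from rnascore import (FixtureSpec, load_model, make_fixture, save_model,
                      scott_bin_width, sippl_smooth, train)
from rnascore.atom_types import N_PAIR_TYPES, atom_type_index, pair_row
from rnascore.errors import ModelFileError
from rnascore.geometry import TORSION_NAMES, backbone_torsions
from rnascore.potential import (DihedralCounts, DistanceCounts,
                                accumulate_dihedral_counts,
                                accumulate_distance_counts,
                                dihedral_energy_table, distance_energy_table,
                                n_dihedral_bins, n_distance_bins)


class TestScottBinWidth:
    def test_direct_evaluations(self):
        assert scott_bin_width(1.0, 1000) == pytest.approx(0.349)
        assert scott_bin_width(2.0, 8) == pytest.approx(3.49)

    def test_linear_in_sigma(self):
        assert scott_bin_width(2.0, 500) == pytest.approx(
            2 * scott_bin_width(1.0, 500))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            scott_bin_width(0.0, 10)
        with pytest.raises(ValueError):
            scott_bin_width(1.0, 0)


class TestDistanceCounts:
    def test_adjacent_backbone_base_pair_not_counted(self):
        # two sequence-adjacent residues: one backbone atom 4 Å from a base
        # atom contributes nothing; the base-base pair at 4.6 Å contributes
        # one count in its bin
        r1 = toy_residue("A", {"O5'": (0, 0, 0), "N9": (0, 4.6, 0)}, 1)
        r2 = toy_residue("U", {"N1": (0, 0, 4.0)}, 2)
        structure = toy_structure([("A", [r1, r2])])
        counts = accumulate_distance_counts([structure], 0.3, 20.0)
        assert counts.total == 1
        row = pair_row(atom_type_index("A", "N9"), atom_type_index("U", "N1"))
        d = math.dist((0, 4.6, 0), (0, 0, 4.0))
        assert counts.counts[row, int(d / 0.3)] == 1

    def test_same_residue_pairs_never_counted(self):
        r1 = toy_residue("A", {"N9": (0, 0, 0), "N1": (0, 4, 0)}, 1)
        structure = toy_structure([("A", [r1])])
        assert accumulate_distance_counts([structure]).total == 0

    def test_different_chains_always_counted(self):
        r1 = toy_residue("A", {"O5'": (0, 0, 0)}, 1)
        r2 = toy_residue("U", {"O5'": (5, 0, 0)}, 1)
        structure = toy_structure([("A", [r1]), ("B", [r2])])
        assert accumulate_distance_counts([structure]).total == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        structure = random_small_fixture(seed)
        counts = accumulate_distance_counts([structure], 0.3, 20.0)
        oracle = oracle_distance_counts([structure], 0.3, 20.0,
                                        N_PAIR_TYPES, n_distance_bins())
        np.testing.assert_array_equal(counts.counts, oracle)

    def test_empty_corpus_gives_zero_counts(self):
        counts = accumulate_distance_counts([])
        assert counts.total == 0
        assert counts.counts.shape == (N_PAIR_TYPES, 67)

    def test_default_binning_has_67_bins_10_penalty(self):
        assert n_distance_bins(0.3, 20.0) == 67
        counts = accumulate_distance_counts([], 0.3, 20.0)
        energy = distance_energy_table(counts, e_max=5.0, clash_penalty=10.0)
        assert np.all(energy[:, :10] == 10.0)
        assert np.all(energy[:, 10:] == 5.0)  # empty corpus: all E_max


class TestDihedralCounts:
    def test_single_gamma_lands_in_bin_12(self):
        counts = DihedralCounts(counts=np.zeros((7, 80), dtype=np.int64),
                                bin_width=4.5)
        row = TORSION_NAMES.index("gamma")
        counts.counts[row, int(54.0 / 4.5)] += 1
        assert counts.counts[row, 12] == 1

    def test_bin_width_4p5_gives_80_bins(self):
        assert n_dihedral_bins(4.5) == 80
        with pytest.raises(ValueError):
            n_dihedral_bins(4.4)

    def test_row_totals_match_direct_scan(self):
        structure, _ = make_fixture(FixtureSpec("duplex", 10, seed=21))
        counts = accumulate_dihedral_counts([structure], 4.5)
        expected = {name: 0 for name in TORSION_NAMES}
        for _, _, ts in backbone_torsions(structure):
            for name in TORSION_NAMES:
                if getattr(ts, name) is not None:
                    expected[name] += 1
        for row, name in enumerate(TORSION_NAMES):
            assert counts.n_i[row] == expected[name]
        assert counts.counts.shape == (7, 80)


class TestEnergyTables:
    def test_rows_proportional_to_pooled_profile_give_zero(self):
        counts = np.outer([1, 2, 4], [3, 1, 2, 4]).astype(np.int64)
        dc = DistanceCounts(counts=np.vstack([counts,
                                              np.zeros((N_PAIR_TYPES - 3, 4),
                                                       dtype=np.int64)]),
                            bin_width=2.0, cutoff=8.0)
        energy = distance_energy_table(dc, e_max=5.0, clash_penalty=10.0)
        # one penalty bin ([0,2) Å); the trained bins of populated rows are 0
        np.testing.assert_allclose(energy[:3, 1:], 0.0, atol=1e-12)
        assert np.all(energy[:, 0] == 10.0)

    def test_worked_ratio_example(self):
        # N_ab(d)=2, N_ab=10, N(d)=5, N=100 -> -ln 4
        counts = np.zeros((N_PAIR_TYPES, 4), dtype=np.int64)
        counts[0] = [2, 4, 2, 2]                      # N_ab = 10
        counts[1] = [3, 40, 30, 17]                   # fills the pool to 100
        dc = DistanceCounts(counts=counts, bin_width=4.0, cutoff=16.0)
        assert dc.total == 100 and dc.n_d[0] == 5
        energy = distance_energy_table(dc, e_max=5.0, clash_penalty=10.0)
        assert energy[0, 0] == pytest.approx(-math.log(4.0))

    def test_zero_count_bins_get_e_max(self):
        counts = np.zeros((N_PAIR_TYPES, 4), dtype=np.int64)
        counts[0] = [5, 0, 5, 5]
        counts[1] = [1, 1, 1, 1]
        dc = DistanceCounts(counts=counts, bin_width=4.0, cutoff=16.0)
        energy = distance_energy_table(dc, e_max=5.0, clash_penalty=10.0)
        assert energy[0, 1] == 5.0

    def test_energy_symmetric_in_pair_order(self):
        a = atom_type_index("A", "N9")
        b = atom_type_index("U", "N1")
        assert pair_row(a, b) == pair_row(b, a)

    def test_dihedral_identical_rows_give_zero(self):
        counts = DihedralCounts(counts=np.tile([4, 2, 8, 2], (7, 1)).astype(np.int64),
                                bin_width=90.0)
        np.testing.assert_allclose(dihedral_energy_table(counts, 5.0), 0.0,
                                   atol=1e-12)

    def test_dihedral_worked_ratio_example(self):
        # N_i(theta)=8, N_i=80, N(theta)=20, N=800 -> -ln 4
        counts = np.zeros((7, 4), dtype=np.int64)
        counts[0] = [8, 24, 24, 24]
        counts[1] = [12, 236, 236, 236]
        counts = DihedralCounts(counts=counts, bin_width=90.0)
        assert counts.total == 800 and counts.n_theta[0] == 20
        energy = dihedral_energy_table(counts, 5.0)
        assert energy[0, 0] == pytest.approx(-math.log(4.0))

    def test_uniform_row_vs_peaked_pool_sign(self):
        # a flat row against a pooled reference peaked in bin 0: the flat
        # row is depleted at the pooled peak (positive energy) and enriched
        # away from it (negative energy)
        counts = np.zeros((7, 4), dtype=np.int64)
        counts[0] = [10, 10, 10, 10]
        counts[1] = [300, 20, 20, 20]
        energy = dihedral_energy_table(DihedralCounts(counts=counts,
                                                      bin_width=90.0), 5.0)
        assert energy[0, 0] > 0
        assert np.all(energy[0, 1:] < 0)


class TestSipplSmoothing:
    def setup_method(self):
        self.pool = np.array([0.5, 0.3, 0.2])
        self.row = np.array([0.1, 0.1, 0.8])

    def test_no_observations_returns_pool(self):
        np.testing.assert_allclose(sippl_smooth(self.pool, self.row, m=0),
                                   self.pool)

    def test_unit_weight_is_elementwise_mean(self):
        out = sippl_smooth(self.pool, self.row, m=50, sigma_s=1.0 / 50.0)
        np.testing.assert_allclose(out, (self.pool + self.row) / 2.0)

    def test_many_observations_converge_to_row(self):
        out = sippl_smooth(self.pool, self.row, m=5e7, sigma_s=1.0 / 50.0)
        np.testing.assert_allclose(out, self.row, atol=1e-5)

    def test_negative_m_rejected(self):
        with pytest.raises(ValueError):
            sippl_smooth(self.pool, self.row, m=-1)


class TestPersistence:
    def test_round_trip_is_exact(self, trained_model, tmp_path):
        model = trained_model
        path = tmp_path / "model.prm"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(model.distance_energy,
                                      loaded.distance_energy)
        np.testing.assert_array_equal(model.dihedral_energy,
                                      loaded.dihedral_energy)
        for attr in ("bin_width", "cutoff", "dihedral_bin_width", "weight",
                     "e_max", "clash_penalty", "temperature", "convention"):
            assert getattr(model, attr) == getattr(loaded, attr)

    def test_version_tamper_rejected(self, trained_model, tmp_path):
        model = trained_model
        path = tmp_path / "model.prm"
        save_model(model, path)
        text = path.read_text().replace("rnascore-potential-1",
                                        "rnascore-potential-999")
        path.write_text(text)
        with pytest.raises(ModelFileError):
            load_model(path)

    def test_truncated_file_rejected(self, trained_model, tmp_path):
        model = trained_model
        path = tmp_path / "model.prm"
        save_model(model, path)
        text = path.read_text()
        path.write_text(text[: int(len(text) * 0.8)])
        with pytest.raises(ModelFileError):
            load_model(path)

    def test_corrupted_value_fails_checksum(self, trained_model, tmp_path):
        model = trained_model
        path = tmp_path / "model.prm"
        save_model(model, path)
        lines = path.read_text().splitlines()
        lines[-1] = lines[-1].rsplit(" ", 1)[0] + " 99.0"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ModelFileError):
            load_model(path)


class TestParameterRecovery:
    def test_pairing_signature_recovered_as_energy_minimum(self):
        """The conserved glycosidic-N contact of A-U pairs (~8.8 Å) must
        surface as the minimum of that pair type's trained energy row."""
        from rnascore import make_training_corpus

        corpus = make_training_corpus(24, seed=19)
        model = train(corpus)
        row = pair_row(atom_type_index("A", "N9"), atom_type_index("U", "N1"))
        energies = model.distance_energy[row]
        trained_region = energies[10:]  # beyond the clash floor
        best_bin = 10 + int(np.argmin(trained_region))
        assert best_bin == int(8.793 / 0.3)  # the bin containing 8.7-9.0 Å
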