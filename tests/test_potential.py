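import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_structure
from modecross.potential import (EvalStats, SurrogatePotential, TablePotential,
                                 build_octree, builtin_surrogate_potential,
                                 load_dfire2_table, normalize_energies,
                                 total_energy_bruteforce, total_energy_octree)
from modecross.structure_io import Atom, Structure


def two_atom_structure(distance, elements=("C", "C"), res_seqs=(1, 3)):
    atoms = [
        Atom(1, f"{elements[0]}A", elements[0], "ALA", "A", res_seqs[0], "",
             np.array([0.0, 0.0, 0.0])),
        Atom(2, f"{elements[1]}B", elements[1], "ALA", "A", res_seqs[1], "",
             np.array([distance, 0.0, 0.0])),
    ]
    return Structure(atoms, id="pair")


class StepPotential(SurrogatePotential):
    """-1 inside 6 A, 0 outside: trivially hand-checkable."""

    def __init__(self, cutoff=6.0):
        super().__init__(cutoff=cutoff)
        self.name = "step"

    def energy_array(self, codes_a, codes_b, distances):
        distances = np.asarray(distances, dtype=float)
        return np.where(distances <= self.cutoff, -1.0, 0.0)


class TestBruteForce:
    def test_single_atom_zero(self):
        s = Structure([Atom(1, "C1", "C", "ALA", "A", 1, "", np.zeros(3))], id="one")
        assert total_energy_bruteforce(s, StepPotential()) == 0.0

    def test_beyond_cutoff_zero(self):
        assert total_energy_bruteforce(two_atom_structure(7.0), StepPotential()) == 0.0

    def test_step_potential_hand_value(self):
        assert total_energy_bruteforce(two_atom_structure(5.0), StepPotential()) == -1.0

    @pytest.mark.parametrize("res_seqs", [(1, 1), (1, 2)])
    def test_near_bonded_pairs_excluded(self, res_seqs):
        s = two_atom_structure(5.0, res_seqs=res_seqs)
        assert total_energy_bruteforce(s, StepPotential()) == 0.0


class TestSurrogate:
    def test_minimum_at_equilibrium_closed_form(self):
        pot = builtin_surrogate_potential(cutoff=10.0)
        d_min, e_min = pot.pair_minimum("C", "C")
        assert d_min == pytest.approx(3.4)
        s = two_atom_structure(d_min)
        assert total_energy_bruteforce(s, pot) == pytest.approx(e_min, abs=1e-12)

    def test_repulsive_core(self):
        pot = builtin_surrogate_potential(cutoff=10.0)
        assert total_energy_bruteforce(two_atom_structure(0.5), pot) > 100.0

    def test_zero_exactly_at_cutoff(self):
        pot = builtin_surrogate_potential(cutoff=10.0)
        e = pot.energy_fn("C", "C", 10.0)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, hinge):
        pot = builtin_surrogate_potential(cutoff=8.0)
        base = total_energy_bruteforce(hinge, pot)
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("zyx", [12, 80, -33], degrees=True).as_matrix()
        moved = hinge.with_coords(hinge.coords @ R.T + np.array([3.0, 4.0, 5.0]))
        assert total_energy_bruteforce(moved, pot) == pytest.approx(base, rel=1e-9)


TOY_TABLE = """\
#bins 0.0 5.0 5.0 10.0
A A -2.0 -0.5
"""


class TestTable:
    def test_toy_lookup(self, tmp_path):
        path = tmp_path / "toy.tsv"
        path.write_text(TOY_TABLE)
        pot = load_dfire2_table(path)
        assert pot.energy_fn("A", "A", 7.0) == -0.5
        assert pot.energy_fn("A", "A", 2.0) == -2.0
        assert pot.energy_fn("A", "A", 12.0) == 0.0

    def test_symmetrized_on_load(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("#bins 0.0 5.0\nA B -1.5\n")
        pot = load_dfire2_table(path)
        for d in (1.0, 4.9):
            assert pot.energy_fn("A", "B", d) == pot.energy_fn("B", "A", d)

    def test_unknown_type_pairs_skipped_and_counted(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("#bins 0.0 8.0\nC C -1.0\n")
        pot = load_dfire2_table(path)
        s = two_atom_structure(5.0, elements=("C", "N"))
        stats = EvalStats()
        assert total_energy_bruteforce(s, pot, stats=stats) == 0.0
        assert stats.unknown_type_pairs == 1

    def test_malformed_tables_rejected(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("A A -1.0\n")
        with pytest.raises(ValueError, match="#bins"):
            load_dfire2_table(bad)
        bad.write_text("#bins 0.0 5.0 6.0 10.0\nA A -1.0 -2.0\n")
        with pytest.raises(ValueError, match="contiguous"):
            load_dfire2_table(bad)


class TestOctree:
    def test_single_atom_root_leaf(self):
        s = Structure([Atom(1, "C1", "C", "ALA", "A", 1, "", np.zeros(3))], id="one")
        tree = build_octree(s)
        assert tree.is_leaf and list(tree.atom_indices) == [0]

    def test_leaves_partition_atoms(self):
        s = random_structure(1000, seed=42)
        tree = build_octree(s, capacity=16)
        seen = []

        def collect(node):
            if node.is_leaf:
                seen.extend(node.atom_indices)
            for c in node.children:
                collect(c)

        collect(tree)
        assert sorted(seen) == list(range(1000))

    def test_leaf_capacity_respected(self):
        s = random_structure(1000, seed=42)
        tree = build_octree(s, capacity=16, max_depth=12)

        def check(node):
            if node.is_leaf:
                assert len(node.atom_indices) <= 16 or node.depth == 12
            for c in node.children:
                check(c)

        check(tree)

    @pytest.mark.parametrize("n_atoms,cutoff", [(10, 4.0), (50, 8.0), (500, 15.0)])
    def test_matches_bruteforce(self, n_atoms, cutoff):
        s = random_structure(n_atoms, seed=n_atoms)
        pot = SurrogatePotential(cutoff=cutoff)
        brute = total_energy_bruteforce(s, pot)
        fast = total_energy_octree(s, pot)
        assert fast == pytest.approx(brute, rel=1e-9, abs=1e-12)

    def test_all_atoms_beyond_cutoff(self):
        coords = 100.0 * np.eye(3)
        atoms = [Atom(i + 1, f"C{i}", "C", "ALA", "A", 2 * i + 1, "", coords[i])
                 for i in range(3)]
        s = Structure(atoms, id="far")
        assert total_energy_octree(s, StepPotential()) == 0.0

    def test_smaller_cutoff_prunes_more_pairs(self, helix):
        wide, narrow = EvalStats(), EvalStats()
        tree = build_octree(helix, capacity=4)
        total_energy_octree(helix, SurrogatePotential(cutoff=15.0), tree, stats=wide)
        total_energy_octree(helix, SurrogatePotential(cutoff=0.1), tree, stats=narrow)
        assert narrow.pairs_evaluated < wide.pairs_evaluated

    def test_subquadratic_pair_scaling(self):
        sizes = (100, 3000)
        counts = []
        for n in sizes:
            stats = EvalStats()
            total_energy_octree(random_structure(n, seed=n),
                                SurrogatePotential(cutoff=4.0), stats=stats)
            counts.append(stats.pairs_evaluated)
        exponent = np.log(counts[1] / counts[0]) / np.log(sizes[1] / sizes[0])
        assert exponent < 1.5

    def test_structure_mismatch_rejected(self, helix, hinge):
        tree = build_octree(helix)
        with pytest.raises(ValueError, match="octree built for"):
            total_energy_octree(hinge, StepPotential(), tree)


class TestNormalize:
    def test_three_point_example(self):
        out = normalize_energies([-50.0, -30.0, -10.0])
        assert np.allclose(out, [0.0, 5.0, 10.0])

    def test_constant_input_maps_to_zero(self):
        assert np.array_equal(normalize_energies([3.3, 3.3, 3.3]), [0.0, 0.0, 0.0])

    # integers scaled down keep the spread well above fp cancellation in a*v+b
    @given(st.lists(st.integers(-10**9, 10**9), min_size=2, unique=True)
           .map(lambda vs: [v * 1e-3 for v in vs]),
           st.floats(0.1, 100.0), st.floats(-1e5, 1e5))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance_and_range(self, values, a, b):
        base = normalize_energies(values)
        scaled = normalize_energies([a * v + b for v in values])
        assert np.allclose(base, scaled, atol=1e-6)
        assert base.min() == pytest.approx(0.0)
        assert base.max() == pytest.approx(10.0)

    def test_rejects_empty_and_nonfinite(self):
        with pytest.raises(ValueError):
            normalize_energies([])
        with pytest.raises(ValueError):
            normalize_energies([1.0, np.nan])
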