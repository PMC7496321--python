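import numpy as np
import pytest

from modecross import enm, protocols
from modecross.potential import EnergyValue, builtin_surrogate_potential
from modecross.protocols import (AmplitudeEnvelope, EnergyMap, EnergySample,
                                 SteepestDescentMinimizer, amplitude_search,
                                 compute_envelope, find_max_amplitude,
                                 identity_minimizer, make_manifest,
                                 p1_conformers, p2_conformers,
                                 read_energy_map_pdb, sample_mode_space,
                                 select_p3_point, write_energy_map_pdb)


class TestAmplitudeSearch:
    def test_permissive_criterion_hits_cap(self):
        assert amplitude_search(lambda a: True, cap=1600.0) == 1600.0

    def test_always_failing_criterion_below_one(self):
        assert amplitude_search(lambda a: False) < 1.0

    @pytest.mark.parametrize("a_star", [10.0, 350.0, 1000.0])
    def test_threshold_oracle_recovered(self, a_star):
        found = amplitude_search(lambda a: a <= a_star, convergence_tol=1.0)
        assert abs(found - a_star) <= 1.0

    def test_trace_matches_hand_simulation(self):
        # pass iff a <= 350: 100 ok, 200 ok, 400 fail, then bisection down to
        # a bracket of width <= 1 around 350; the largest passing value is 350.
        trials = []

        def crit(a):
            trials.append(a)
            return a <= 350.0

        found = amplitude_search(crit, convergence_tol=1.0)
        assert trials[:4] == [100.0, 200.0, 400.0, 300.0]
        assert found == pytest.approx(350.0, abs=1.0)

    def test_find_max_amplitude_signed(self, hinge, hinge_modes):
        v = find_max_amplitude(hinge, hinge_modes, 0, -1,
                               criterion=lambda a: a <= 40.0)
        assert v == pytest.approx(-40.0, abs=1.0)
        assert v <= 0

    def test_structural_criterion_runs(self, helix):
        modes = enm.compute_modes(helix, 1)
        v = find_max_amplitude(helix, modes, 0, +1, identity_minimizer,
                               ss_tolerance_pct=10.0)
        # deforming far along a mode eventually unwinds the helix
        assert 0 <= v < 1600.0

    def test_bad_direction_and_mode_index(self, hinge, hinge_modes):
        with pytest.raises(ValueError):
            find_max_amplitude(hinge, hinge_modes, 0, 2)
        with pytest.raises(IndexError):
            find_max_amplitude(hinge, hinge_modes, 9, 1)


class TestMinimizer:
    def test_descent_reduces_surrogate_energy(self, hinge, hinge_modes):
        from modecross.potential import total_energy_bruteforce
        pot = builtin_surrogate_potential(cutoff=8.0)
        strained = enm.deform(hinge, hinge_modes, [60.0])
        minimizer = SteepestDescentMinimizer(n_steps=50)
        relaxed = minimizer(strained)
        assert relaxed.n_atoms == strained.n_atoms
        assert (total_energy_bruteforce(relaxed, minimizer.potential)
                <= total_energy_bruteforce(strained, minimizer.potential))

    def test_descent_deterministic(self, hinge):
        minimizer = SteepestDescentMinimizer(n_steps=20)
        assert np.array_equal(minimizer(hinge).coords, minimizer(hinge).coords)


class TestP1:
    def test_six_labeled_conformers(self, hinge, helix, hinge_modes):
        modes_l = enm.compute_modes(helix, 3)
        conf = p1_conformers(hinge, helix, hinge_modes, modes_l)
        assert set(conf) == {"Ru", "R+", "R-", "Lu", "L+", "L-"}
        assert np.array_equal(conf["Ru"].coords, hinge.coords)

    def test_permissive_tolerance_reaches_cap(self, hinge, helix, hinge_modes):
        modes_l = enm.compute_modes(helix, 3)
        conf = p1_conformers(hinge, helix, hinge_modes, modes_l,
                             ss_tolerance_pct=100.0, cap=200.0)
        expected = enm.deform(hinge, hinge_modes, [200.0])
        assert np.allclose(conf["R+"].coords, expected.coords, atol=1e-9)
        expected_neg = enm.deform(hinge, hinge_modes, [-200.0])
        assert np.allclose(conf["R-"].coords, expected_neg.coords, atol=1e-9)


class TestP2:
    def test_unbound_equals_bound_gives_unbound(self, hinge, helix, hinge_modes):
        modes_l = enm.compute_modes(helix, 3)
        result = p2_conformers(hinge, hinge.coords, helix, helix.coords,
                               hinge_modes, modes_l)
        assert np.allclose(result.conformers["R_theor"].coords, hinge.coords,
                           atol=1e-9)
        assert np.allclose(result.amplitudes["L_theor"], 0.0, atol=1e-9)

    def test_reproduces_pseudo_bound_in_mode_span(self, hinge, helix, hinge_modes):
        modes_l = enm.compute_modes(helix, 3)
        amps = np.array([4.0, -1.0, 6.0])
        pseudo = enm.deform(hinge, hinge_modes, amps)
        result = p2_conformers(hinge, pseudo.coords, helix, helix.coords,
                               hinge_modes, modes_l)
        rmsd = np.sqrt(np.mean(np.sum(
            (result.conformers["R_theor"].coords - pseudo.coords) ** 2, axis=1)))
        assert rmsd < 1e-6
        direct = enm.project_displacement(hinge_modes, hinge, pseudo.coords)
        assert np.allclose(result.amplitudes["R_theor"], direct, atol=1e-12)


def small_envelope(limit=20.0):
    return AmplitudeEnvelope(limits=((0, limit, -limit), (1, limit, -limit),
                                     (2, limit, -limit)))


class TestSampling:
    def test_grid_counting_and_origin(self, hinge, hinge_modes):
        pot = builtin_surrogate_potential(cutoff=8.0)
        emap = sample_mode_space(hinge, hinge_modes, small_envelope(),
                                 (3, 3, 3), pot)
        assert len(emap.samples) == 27  # symmetric envelope: origin on-grid
        assert not emap.origin_injected
        origin = [s for s in emap.samples if s.amplitudes == (0.0, 0.0, 0.0)]
        assert len(origin) == 1 and origin[0].ss_pct == 100.0

    def test_origin_injected_for_asymmetric_grid(self, hinge, hinge_modes):
        pot = builtin_surrogate_potential(cutoff=8.0)
        env = AmplitudeEnvelope(limits=((0, 30.0, -10.0), (1, 30.0, -10.0),
                                        (2, 30.0, -10.0)))
        emap = sample_mode_space(hinge, hinge_modes, env, (3, 3, 3), pot)
        assert emap.origin_injected
        assert len(emap.samples) == 28

    def test_origin_energy_matches_unmodified_input(self, hinge, hinge_modes):
        from modecross.potential import total_energy_bruteforce
        pot = builtin_surrogate_potential(cutoff=8.0)
        emap = sample_mode_space(hinge, hinge_modes, small_envelope(),
                                 (3, 3, 3), pot)
        origin = next(s for s in emap.samples if s.amplitudes == (0.0, 0.0, 0.0))
        assert origin.energy.raw == pytest.approx(
            total_energy_bruteforce(hinge, pot), rel=1e-9)

    def test_normalized_span(self, hinge, hinge_modes):
        pot = builtin_surrogate_potential(cutoff=8.0)
        emap = sample_mode_space(hinge, hinge_modes, small_envelope(),
                                 (3, 3, 3), pot)
        values = [s.energy.normalized for s in emap.samples]
        assert min(values) == 0.0
        assert max(values) == 10.0


def make_map(samples):
    n = len(samples)
    return EnergyMap(grid=((0.0, float(n - 1), 1.0), (0.0, 0.0, 0.0),
                           (0.0, 0.0, 0.0)), samples=tuple(samples))


def sample(amps, normalized, ss=100.0):
    return EnergySample(amplitudes=tuple(map(float, amps)),
                        energy=EnergyValue(raw=normalized, normalized=normalized),
                        ss_pct=ss)


class TestSelection:
    def test_only_origin_qualifies(self):
        emap = make_map([sample((0, 0, 0), 0.0),
                         sample((9, 9, 9), 9.9),          # too high energy
                         sample((8, 8, 8), 1.0, ss=50.0)])  # unwound
        sel = select_p3_point(emap)
        assert sel.amplitudes == (0.0, 0.0, 0.0)
        assert not sel.fallback_to_origin

    def test_nothing_qualifies_falls_back(self):
        emap = make_map([sample((1, 1, 1), 9.0), sample((2, 2, 2), 8.0)])
        sel = select_p3_point(emap)
        assert sel.fallback_to_origin
        assert sel.amplitudes == (0.0, 0.0, 0.0)

    def test_hand_built_tie_break(self):
        # qualifying norms {5, 13, 13}; the norm-13 pair tie-breaks on energy
        samples = [sample((3, 4, 0), 1.0),
                   sample((5, 12, 0), 2.0),
                   sample((12, 5, 0), 3.0)]
        samples += [sample((30, 30, 30), 9.5) for _ in range(0)]
        emap = make_map(samples)
        sel = select_p3_point(emap)
        assert sel.amplitudes == (5.0, 12.0, 0.0)

    def test_threshold_relaxation_is_monotone(self):
        rng = np.random.default_rng(5)
        samples = [sample(rng.uniform(-20, 20, 3), rng.uniform(0, 10),
                          rng.uniform(85, 100)) for _ in range(40)]
        samples.append(sample((0, 0, 0), 0.0))
        emap = make_map(samples)
        n5 = np.linalg.norm(select_p3_point(emap, 5.0).amplitudes)
        n10 = np.linalg.norm(select_p3_point(emap, 10.0).amplitudes)
        assert n10 >= n5

    def test_matches_exhaustive_oracle_on_random_maps(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            samples = [sample(rng.uniform(-50, 50, 3),
                              round(rng.uniform(0, 10), 3),
                              round(rng.uniform(80, 100), 2))
                       for _ in range(30)]
            emap = make_map(samples)
            sel = select_p3_point(emap, 5.0, 90.0)
            qualifying = [s for s in samples
                          if s.energy.normalized <= 5.0 and s.ss_pct >= 90.0]
            if not qualifying:
                assert sel.fallback_to_origin
                continue
            best = None
            for s in qualifying:
                key = (-s.norm, s.energy.normalized, s.amplitudes)
                if best is None or key < best[0]:
                    best = (key, s)
            assert sel.amplitudes == best[1].amplitudes

    def test_envelope_growth_never_shrinks_selection(self, hinge, hinge_modes):
        pot = builtin_surrogate_potential(cutoff=8.0)
        small = sample_mode_space(hinge, hinge_modes, small_envelope(10.0),
                                  (3, 3, 3), pot)
        # 5-point axes over double the range contain the small grid's points
        large = sample_mode_space(hinge, hinge_modes, small_envelope(20.0),
                                  (5, 5, 5), pot)
        merged_raw = [s.energy.raw for s in small.samples] + \
                     [s.energy.raw for s in large.samples]
        # compare on a shared normalization to isolate the feasible-set effect
        from modecross.potential import normalize_energies
        norm = normalize_energies(merged_raw)
        n_small = len(small.samples)

        def renorm(emap, offset):
            return EnergyMap(grid=emap.grid, samples=tuple(
                EnergySample(s.amplitudes,
                             EnergyValue(s.energy.raw, float(norm[offset + i])),
                             s.ss_pct)
                for i, s in enumerate(emap.samples)),
                origin_injected=emap.origin_injected)

        sel_small = select_p3_point(renorm(small, 0))
        sel_large = select_p3_point(renorm(large, n_small))
        assert np.linalg.norm(sel_large.amplitudes) >= \
            np.linalg.norm(sel_small.amplitudes) - 1e-9


class TestManifest:
    def test_paper_pair_lists(self):
        assert make_manifest("P0").pairs == (("Ru", "Lu"),)
        assert make_manifest("P1").pairs == (
            ("Ru", "Lu"), ("Ru", "L+"), ("Ru", "L-"),
            ("R+", "Lu"), ("R+", "L+"), ("R+", "L-"),
            ("R-", "Lu"), ("R-", "L+"), ("R-", "L-"))
        assert make_manifest("P2").pairs == (("R_theor", "L_theor"),)
        assert make_manifest("P3").pairs == (
            ("R5", "L5"), ("Ru", "L5"), ("R5", "Lu"), ("Ru", "Lu"))

    @pytest.mark.parametrize("protocol,count", [("P0", 1), ("P1", 9),
                                                ("P2", 1), ("P3", 4)])
    def test_cardinalities(self, protocol, count):
        assert len(make_manifest(protocol).pairs) == count

    def test_unknown_protocol(self):
        with pytest.raises(ValueError, match="unknown protocol"):
            make_manifest("P4")

    def test_tsv_export(self, tmp_path):
        path = tmp_path / "m.tsv"
        make_manifest("P3").write_tsv(path, paths={"R5": "R5.pdb"})
        lines = path.read_text().splitlines()
        assert len(lines) == 5
        assert lines[1].startswith("R5\tL5\tR5.pdb")


class TestEnergyMapExport:
    def test_pdb_like_roundtrip(self, hinge, hinge_modes, tmp_path):
        pot = builtin_surrogate_potential(cutoff=8.0)
        emap = sample_mode_space(hinge, hinge_modes, small_envelope(),
                                 (3, 3, 3), pot)
        path = tmp_path / "map.pdb"
        write_energy_map_pdb(emap, path)
        text = path.read_text()
        assert sum(1 for l in text.splitlines() if l.startswith("ATOM")) == 27
        assert "AMPLITUDE SCALE" in text
        scale, rows = read_energy_map_pdb(path)
        for s, (amps, b) in zip(emap.samples, rows):
            assert np.allclose(amps, s.amplitudes, atol=0.01 * max(scale, 1.0))
            assert b == pytest.approx(s.energy.normalized, abs=0.005)

    def test_large_amplitudes_get_scaled(self, tmp_path):
        samples = [sample((5000.0, 0.0, 0.0), 1.0), sample((0.0, 0.0, 0.0), 0.0)]
        emap = make_map(samples)
        path = tmp_path / "map.pdb"
        write_energy_map_pdb(emap, path)
        scale, rows = read_energy_map_pdb(path)
        assert scale == 10.0
        assert rows[0][0][0] == pytest.approx(5000.0, abs=0.01 * scale)
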