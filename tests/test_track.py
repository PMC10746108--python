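"""Track generator: LET table, determinism, event patterns, MI channel,
solution composition."""

import numpy as np
import pytest

import trackchem as tc


class TestLetTable:
    @pytest.mark.parametrize(
        "energy, let", [(500.0, 9.3), (300.0, 11.7), (70.0, 34.5), (6.0, 248.0)]
    )
    def test_anchor_energies(self, energy, let):
        assert tc.let_for_energy(energy) == pytest.approx(let)

    def test_monotone_decreasing_in_energy(self):
        energies = np.geomspace(6.0, 500.0, 40)
        lets = [tc.let_for_energy(e) for e in energies]
        assert all(a > b for a, b in zip(lets, lets[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tc.let_for_energy(1000.0)
        with pytest.raises(ValueError):
            tc.let_for_energy(1.0)

    def test_beam_requires_exactly_one_of_energy_let(self):
        with pytest.raises(ValueError):
            tc.BeamSpec(energy_per_nucleon=500.0, let_value=9.3)
        with pytest.raises(ValueError):
            tc.BeamSpec()


class TestSolution:
    def test_standard_fricke_composition(self, fricke):
        assert fricke.conc("Fe2+") == 1.0e-3
        assert fricke.conc("O2") == 2.5e-4
        # complete first + partial second dissociation of 0.4 M H2SO4
        assert fricke.conc("H3O+") == pytest.approx(0.411, rel=0.01)
        assert fricke.ionic_strength == pytest.approx(0.427, rel=0.01)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            tc.BulkSolution.fricke(-1.0)
        with pytest.raises(ValueError):
            tc.BulkSolution(concentrations={"O2": -1e-3})

    def test_cystamine_ionic_strength_opt_in(self):
        base = tc.BulkSolution.fricke(1.0)
        salted = tc.BulkSolution.fricke(
            1.0, count_cystamine_in_ionic_strength=True
        )
        assert salted.ionic_strength == pytest.approx(base.ionic_strength + 3.0)


class TestGenerateTrack:
    def test_same_seed_identical(self, params):
        beam = tc.BeamSpec(let_value=34.5)
        a = tc.generate_track(beam, params, seed=7, target_particles=2000)
        b = tc.generate_track(beam, params, seed=7, target_particles=2000)
        np.testing.assert_array_equal(a.species, b.species)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert a.deposited_energy == b.deposited_energy

    def test_deposited_energy_matches_let_times_length(self, params):
        beam = tc.BeamSpec(let_value=248.0, segment_length=1.5)
        seg = tc.generate_track(beam, params, seed=3)
        expected = 248.0e3 * 1.5  # eV
        assert seg.deposited_energy == pytest.approx(expected, rel=0.05)

    def test_particle_count_tracks_deposited_energy(self, params):
        counts = []
        for let, length in [(34.5, 2.0), (34.5, 4.0), (69.0, 2.0)]:
            seg = tc.generate_track(
                tc.BeamSpec(let_value=let, segment_length=length), params, seed=5
            )
            counts.append(seg.n_particles / (let * length))
        assert max(counts) / min(counts) == pytest.approx(1.0, rel=0.1)

    def test_initial_yields_match_parameters(self, params, small_track):
        y = small_track.initial_yields()
        assert y["e_aq"] == pytest.approx(params.initial_yields_1ps["e_aq"], rel=0.1)
        assert y["OH"] == pytest.approx(params.initial_yields_1ps["OH"], rel=0.1)

    def test_inventory_is_charge_neutral(self, small_track, network):
        charge = sum(
            network.spec(small_track.species_names[c]).charge
            for c in small_track.species
        )
        assert charge == 0

    def test_mi_disabled_means_no_oxygen_atoms(self, small_track):
        assert "O3P" not in small_track.species_names

    def test_mi_replaces_oh_with_oxygen_atoms(self, params):
        from dataclasses import replace

        beam = tc.BeamSpec(let_value=248.0)
        off = tc.generate_track(beam, params, seed=11, target_particles=4000)
        on = tc.generate_track(
            beam, replace(params, mi_probability=0.2), seed=11,
            target_particles=4000,
        )
        y_off, y_on = off.initial_yields(), on.initial_yields()
        assert y_on.get("O3P", 0.0) > 0.05
        assert y_on["OH"] < y_off["OH"]
        # charge neutrality holds with the MI pattern too
        net = tc.load_scheme()
        charge = sum(net.spec(on.species_names[c]).charge for c in on.species)
        assert charge == 0

    def test_zero_let_rejected(self, params):
        with pytest.raises(ValueError):
            tc.generate_track(tc.BeamSpec(let_value=0.0), params, seed=1)

    def test_empty_yields_rejected(self):
        with pytest.raises(ValueError):
            tc.TrackModelParams(initial_yields_1ps={"e_aq": -1.0})
        params = tc.TrackModelParams(
            initial_yields_1ps={"e_aq": 0.0, "H": 0.0, "H2": 0.0}
        )
        with pytest.raises(ValueError):
            tc.generate_track(tc.BeamSpec(let_value=9.3), params, seed=1)

    def test_inconsistent_yield_table_rejected(self):
        with pytest.raises(ValueError, match="OH"):
            tc.TrackModelParams(
                initial_yields_1ps={"e_aq": 4.0, "H": 0.5, "OH": 9.9}
            )

    def test_radial_concentration_rises_with_let(self, params):
        """Spur strings merge into a dense column as LET grows: the linear
        density of species inside a thin cylinder around the axis rises
        much faster than the overall count."""
        dens = {}
        for let in (9.3, 248.0):
            seg = tc.generate_track(
                tc.BeamSpec(let_value=let), params, seed=9, target_particles=4000
            )
            radial = np.linalg.norm(seg.positions[:, 1:], axis=1)
            core = radial < 5.0
            dens[let] = core.sum() / seg.segment_length_nm
        assert dens[248.0] > 10 * dens[9.3]


class TestCalibration:
    def test_zero_budget_rejected(self, network, fricke):
        with pytest.raises(ValueError):
            tc.calibrate_track_model(
                {9.3: 13.3}, network=network, solution=fricke, max_evals=0
            )

    def test_grid_search_returns_best(self, network, fricke):
        res = tc.calibrate_track_model(
            {9.3: 13.3},
            network=network,
            solution=fricke,
            grid={"spur_radius_sigma": [1.0, 5.0]},
            replicates=1,
            target_particles=800,
            max_evals=4,
        )
        assert len(res.history) == 2
        best_sse = min(s for _, s in res.history)
        assert res.objective == best_sse
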