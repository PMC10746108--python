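"""IRT engine: first-passage sampling against the closed form and a
Brownian-dynamics oracle, scavenging times, and the event-driven stage."""

import numpy as np
import pytest

import trackchem as tc
from trackchem.irt import _sample_pair_times

from _bd_oracle import bd_pair_survival


class TestPairTimeSampler:
    def test_contact_reacts_immediately(self):
        rng = np.random.default_rng(1)
        assert tc.sample_pair_reaction_time(1.0, 1.0, 1e9, rng) == 0.0
        assert tc.sample_pair_reaction_time(0.5, 1.0, 1e9, rng) == 0.0

    def test_ultimate_probability_is_r_over_r0(self):
        """An isolated pair at r0 = 2R reacts with probability 1/2."""
        rng = np.random.default_rng(2)
        n = 100_000
        u = rng.random(n)
        t = _sample_pair_times(
            np.full(n, 2.0), np.full(n, 1.0), 1.0e9, u
        )
        p = np.isfinite(t).mean()
        assert p == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))

    def test_sampled_cdf_matches_closed_form(self):
        """Empirical CDF of 1e5 draws vs W(t) = (R/r0) erfc((r0-R)/2 sqrt(Dt))."""
        from scipy.special import erfc

        rng = np.random.default_rng(3)
        r0, big_r, d = 2.0, 1.0, 1.0e9  # nm, nm, nm^2/s
        n = 100_000
        t = _sample_pair_times(
            np.full(n, r0), np.full(n, big_r), d, rng.random(n)
        )
        for tt in np.geomspace(1e-11, 1e-7, 8):
            w = (big_r / r0) * erfc((r0 - big_r) / (2 * np.sqrt(d * tt)))
            emp = (t <= tt).mean()
            assert emp == pytest.approx(w, abs=3 * np.sqrt(w * (1 - w) / n) + 1e-4)

    def test_matches_brownian_dynamics_oracle(self):
        """IRT survival vs a random-flight walker with absorbing contact."""
        rng = np.random.default_rng(4)
        r0, big_r, d = 2.0, 1.0, 1.0e9
        n = 100_000
        t = _sample_pair_times(
            np.full(n, r0), np.full(n, big_r), d, rng.random(n)
        )
        t_grid = np.array([3e-10, 1e-9, 3e-9, 1e-8, 1e-7])
        n_bd = 20_000
        surv_bd = bd_pair_survival(
            r0, big_r, d, t_grid, n_walkers=n_bd, rng=5
        )
        for tt, sb in zip(t_grid, surv_bd):
            si = (t > tt).mean()
            tol = 3 * np.sqrt(sb * (1 - sb) / n_bd + si * (1 - si) / n)
            assert si == pytest.approx(sb, abs=tol + 0.005)

    def test_invalid_geometry_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            tc.sample_pair_reaction_time(2.0, 0.0, 1e9, rng)
        with pytest.raises(ValueError):
            tc.sample_pair_reaction_time(2.0, 1.0, -1e9, rng)


class TestScavengingSampler:
    def test_zero_power_never_reacts(self):
        assert np.isinf(tc.sample_scavenging_time(0.0, np.random.default_rng(1)))

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            tc.sample_scavenging_time(-1.0, np.random.default_rng(1))

    def test_mean_matches_inverse_scavenging_power(self):
        """Electron capture by 1e-4 M cystamine: mean time ~0.24 us."""
        rng = np.random.default_rng(7)
        power = 4.1e10 * 1e-4
        times = np.array(
            [tc.sample_scavenging_time(power, rng) for _ in range(50_000)]
        )
        assert times.mean() * 1e6 == pytest.approx(0.244, rel=0.02)
        assert np.median(times) / times.mean() == pytest.approx(np.log(2), rel=0.03)


class TestTrackStage:
    def test_empty_track_gives_empty_log(self, network, fricke):
        seg = tc.TrackSegment(
            beam=tc.BeamSpec(let_value=9.3),
            let_value=9.3,
            segment_length_nm=100.0,
            deposited_energy=100.0,
            total_energy=100.0,
            species_names=[],
            species=np.empty(0, np.int32),
            positions=np.empty((0, 3)),
            weights=np.empty(0),
        )
        log = tc.run_track_stage(seg, network, fricke, 1e-6, np.random.default_rng(1))
        assert log.n_events == 0
        assert log.survivor_yields() == {}

    def test_unknown_species_rejected(self, network, fricke):
        seg = tc.TrackSegment(
            beam=tc.BeamSpec(let_value=9.3),
            let_value=9.3,
            segment_length_nm=100.0,
            deposited_energy=100.0,
            total_energy=100.0,
            species_names=["Xx"],
            species=np.zeros(1, np.int32),
            positions=np.zeros((1, 3)),
            weights=np.ones(1),
        )
        with pytest.raises(ValueError, match="Xx"):
            tc.run_track_stage(seg, network, fricke, 1e-6, np.random.default_rng(1))

    def test_event_times_nondecreasing(self, small_log):
        assert small_log.n_events > 100
        assert np.all(np.diff(small_log.times) >= 0)

    def test_element_and_charge_conservation(self, small_log, network):
        tc.verify_conservation(small_log, network)

    def test_isolated_pair_survival(self, network, fricke):
        """Two OH radicals at a known separation: engine-level reaction
        frequency equals the closed-form ultimate probability R/r0 (times
        the small correction from competing Fe2+ scavenging)."""
        rng = np.random.default_rng(8)
        reacted = 0
        n_trials = 400
        r0 = 1.0
        for k in range(n_trials):
            seg = tc.TrackSegment(
                beam=tc.BeamSpec(let_value=9.3),
                let_value=9.3,
                segment_length_nm=100.0,
                deposited_energy=100.0,
                total_energy=100.0,
                species_names=["OH"],
                species=np.zeros(2, np.int32),
                positions=np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]),
                weights=np.ones(2),
            )
            log = tc.run_track_stage(seg, network, fricke, 1e-6, rng)
            reacted += int((log.reaction_ids == 3).sum())
        from trackchem.network import effective_k
        from trackchem.units import k_molar_to_per_molecule

        r = network.reaction(3)
        d_mut = 2 * network.spec("OH").d_nm2_s
        big_r = k_molar_to_per_molecule(
            effective_k(network, r, fricke.ionic_strength)
        ) / (4 * np.pi * d_mut)
        p_expected = big_r / r0
        p = reacted / n_trials
        assert p == pytest.approx(
            p_expected, abs=3 * np.sqrt(p_expected / n_trials) + 0.02
        )

    def test_h_atoms_convert_to_ho2_near_quarter_microsecond(
        self, network, fricke
    ):
        """Isolated H atoms + 2.5e-4 M O2: conversion times concentrate
        around 1/(k[O2]) ~ 0.2 us."""
        rng = np.random.default_rng(9)
        n = 400
        seg = tc.TrackSegment(
            beam=tc.BeamSpec(let_value=9.3),
            let_value=9.3,
            segment_length_nm=1e6,
            deposited_energy=100.0 * n,
            total_energy=100.0 * n,
            species_names=["H"],
            species=np.zeros(n, np.int32),
            positions=np.column_stack(
                [np.linspace(0, 1e6, n), np.zeros((n, 2))]
            ),
            weights=np.ones(n),
        )
        log = tc.run_track_stage(seg, network, fricke, 1e-5, rng)
        t112 = log.times[log.reaction_ids == 112]
        expected_mean = 1.0 / (2.1e10 * 2.5e-4)
        assert len(t112) > 0.9 * n
        assert t112.mean() == pytest.approx(expected_mean, rel=0.15)


class TestYieldTable:
    def test_single_event_definition(self, network):
        """One ferric ion from a 100 eV deposit is G = 1 per 100 eV."""
        log = tc.EventLog(
            species_names=list(network.species),
            initial_counts=np.zeros(len(network.species)),
            deposited_energy=100.0,
            t_handoff=1e-6,
            times=np.array([1e-8]),
            reaction_ids=np.array([6]),
            weights=np.array([1.0]),
            delta_event=np.array([0]),
            delta_code=np.array([list(network.species).index("Fe3+")]),
            delta_count=np.array([1.0]),
        )
        table = tc.time_dependent_yields(log, 100.0, np.array([1e-9, 1e-7]))
        np.testing.assert_allclose(table.g("Fe3+"), [0.0, 1.0])

    def test_channel_extents_sum_to_total(self, small_log, network):
        table = tc.time_dependent_yields(
            small_log, small_log.deposited_energy, np.geomspace(1e-12, 1e-6, 40)
        )
        channels = table.fe3_channels(network)
        total = sum(channels.values())
        np.testing.assert_allclose(total, table.g("Fe3+"), atol=1e-9)

    def test_ferric_yield_monotone(self, small_log):
        table = tc.time_dependent_yields(
            small_log, small_log.deposited_energy, np.geomspace(1e-12, 1e-6, 40)
        )
        assert np.all(np.diff(table.g("Fe3+")) >= -1e-12)

    def test_time_beyond_handoff_flagged(self, small_log):
        with pytest.raises(ValueError):
            tc.time_dependent_yields(
                small_log, small_log.deposited_energy, np.array([1e-3])
            )
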