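"""Reaction-network module: default scheme content, validation, and the
rate/scavenging arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trackchem as tc
from trackchem.network import SchemeError, diffusion_limited_k

PRINTED_K25 = {
    6: 3.4e8, 7: 7.9e5, 8: 52.0, 9: 1.3e7,
    10: 4.1e10, 11: 8.0e9, 12: 1.7e10, 13: 4.2e9, 14: 2.0e9,
    15: 1.0e7, 16: 2.5e8, 17: 1.0e6, 18: 2.0e9, 19: 7.9e5,
    20: 2.0e6, 21: 2.5e9,
}


class TestDefaultScheme:
    @pytest.mark.parametrize("rid, k", sorted(PRINTED_K25.items()))
    def test_printed_rate_constants(self, network, rid, k):
        assert network.reaction(rid).k25 == k

    def test_oh_competition_ratio(self, network):
        """Cystamine outcompetes ferrous for OH by a factor of 50."""
        assert network.reaction(12).k25 / network.reaction(6).k25 == 50.0

    def test_ferric_is_terminal(self, network):
        producers = network.producers_of("Fe3+")
        assert len(producers) >= 6
        assert network.reactions_of("Fe3+") == []

    def test_every_reaction_balances(self, network):
        # validation runs in the constructor; reaching here means it passed
        assert len(network.reactions) > 40

    def test_undeclared_species_rejected(self):
        doc = {
            "include_default": True,
            "reactions": [
                {"id": 900, "reactants": ["OH", "X"], "products": ["OH-"],
                 "k25": 1e9}
            ],
        }
        with pytest.raises(SchemeError, match="900"):
            tc.load_scheme(doc)

    def test_unbalanced_reaction_rejected(self):
        doc = {
            "include_default": True,
            "reactions": [
                {"id": 901, "reactants": ["OH", "OH"], "products": ["H2"],
                 "k25": 1e9}
            ],
        }
        with pytest.raises(SchemeError, match="901"):
            tc.load_scheme(doc)

    def test_user_scheme_extends_defaults(self, network):
        doc = {
            "include_default": True,
            "reactions": [
                {"id": 8, "reactants": ["H2O2", "Fe2+"],
                 "products": ["Fe3+", "OH", "OH-"], "k25": 60.0,
                 "kinetic_class": "bulk-pseudo-first-order"}
            ],
        }
        net = tc.load_scheme(doc)
        assert net.reaction(8).k25 == 60.0
        assert len(net.reactions) == len(network.reactions)


class TestIonicStrength:
    def test_identity_cases(self):
        assert tc.correct_for_ionic_strength(1e9, 0, 2, 0.5) == 1e9
        assert tc.correct_for_ionic_strength(1e9, 1, 2, 0.0) == 1e9

    def test_known_factor(self):
        # z_a z_b = +2 at I = 0.1: 10**(1.02*2*(0.3162/1.3162)) ~ 3.09
        k = tc.correct_for_ionic_strength(1.0, 1, 2, 0.1)
        expected = 10 ** (1.02 * 2 * (np.sqrt(0.1) / (1 + np.sqrt(0.1))))
        assert k == pytest.approx(expected)
        assert k == pytest.approx(3.09, rel=0.01)

    @given(
        za=st.integers(-3, 3), zb=st.integers(-3, 3),
        i1=st.floats(1e-4, 2.0), i2=st.floats(1e-4, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_monotonicity(self, za, zb, i1, i2):
        k1 = tc.correct_for_ionic_strength(1.0, za, zb, i1)
        assert k1 == pytest.approx(tc.correct_for_ionic_strength(1.0, zb, za, i1))
        k2 = tc.correct_for_ionic_strength(1.0, za, zb, i2)
        if za * zb > 0:
            assert (k1 <= k2) == (i1 <= i2)
        elif za * zb < 0:
            assert (k1 >= k2) == (i1 <= i2)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            tc.correct_for_ionic_strength(1e9, 1, 1, -0.1)

    def test_electron_self_recombination_exempt(self, network, fricke):
        r = network.reaction(101)
        assert r.ionic_strength_exempt
        assert tc.effective_k(network, r, fricke.ionic_strength) == r.k25

    def test_diffusion_cap(self, network, fricke):
        # the +3/+3 radical-cation disproportionation would be boosted
        # ~4000-fold; the cap holds it at diffusion control for a 1 nm radius
        r = network.reaction(21)
        a, b = (network.spec(s) for s in r.reactants)
        k = tc.effective_k(network, r, fricke.ionic_strength)
        assert k == pytest.approx(
            diffusion_limited_k(a.d_nm2_s + b.d_nm2_s, 1.0)
        )


class TestScavengingArithmetic:
    @pytest.mark.parametrize(
        "k, c, expected_us",
        [(4.1e10, 1e-4, 0.244), (8.0e9, 1e-4, 1.25), (1.7e10, 1e-4, 0.588)],
    )
    def test_scavenging_times_at_1e4_molar(self, k, c, expected_us):
        """Electron/H/OH capture by 1e-4 M cystamine: ~0.25, 1.25, 0.6 us."""
        assert tc.scavenging_time(k, c) * 1e6 == pytest.approx(expected_us, rel=0.01)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            tc.scavenging_time(0.0, 1e-3)
        with pytest.raises(ValueError):
            tc.scavenging_time(1e9, 0.0)

    def test_oh_branching_between_ferrous_and_cystamine(self):
        # 1 mM each: fraction to Fe2+ = 3.4e8 / (3.4e8 + 1.7e10) = 1/51
        f = tc.branching_fractions([(3.4e8, 1e-3), (1.7e10, 1e-3)])
        assert f[0] == pytest.approx(1 / 51)
        assert f[0] <= 0.02

    def test_single_and_symmetric_channels(self):
        assert tc.branching_fractions([(1e9, 1e-3)])[0] == 1.0
        np.testing.assert_allclose(
            tc.branching_fractions([(2e9, 1e-3), (1e9, 2e-3)]), [0.5, 0.5]
        )

    @given(st.lists(st.tuples(st.floats(0, 1e10), st.floats(0, 1.0)), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_fractions_sum_to_one(self, channels):
        if sum(k * c for k, c in channels) <= 0:
            with pytest.raises(ValueError):
                tc.branching_fractions(channels)
        else:
            assert tc.branching_fractions(channels).sum() == pytest.approx(1.0, abs=1e-12)


class TestEncounterRadius:
    def test_inversion_identity(self):
        d = 5.0e9  # nm^2/s
        k_diff = diffusion_limited_k(d, 1.0)
        assert tc.diffusion_reaction_radius(k_diff, d) == pytest.approx(1.0)

    def test_cystamine_oh_radius(self):
        # k12 with D_mutual = 5e-9 m^2/s -> ~0.45 nm
        r = tc.diffusion_reaction_radius(1.7e10, 5.0e9)
        assert r == pytest.approx(0.449, rel=0.01)

    def test_inverse_proportionality_in_d(self):
        r1 = tc.diffusion_reaction_radius(1e10, 2.0e9)
        r2 = tc.diffusion_reaction_radius(1e10, 4.0e9)
        assert r1 == pytest.approx(2 * r2)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            tc.diffusion_reaction_radius(-1.0, 1e9)
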