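"""Chemical species descriptors.

A :class:`SpeciesSpec` is the mobile unit of the stochastic stage: a name, an
integer charge, a diffusion coefficient and an elemental composition used for
per-reaction balance checks.  Species marked ``is_bulk`` are background
solutes (H3O+, Fe2+, O2, cystamine, ...) treated at fixed concentration and
never simulated as discrete particles.

Naming conventions follow the radiation-chemistry literature, with plain
ASCII identifiers: ``e_aq``, ``OH``, ``H3O+``, ``O2-``, ``O3P`` (ground-state
oxygen atom), ``RSSR`` (doubly protonated cystamine), ``RSSR+`` (its radical
cation, net charge +3), ``RS`` (protonated thiyl radical, net charge +1), etc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .units import D_UNIT_TO_NM2_S

#: elements tracked by the balance checker (charge is tracked separately)
ELEMENTS = ("H", "O", "C", "N", "S", "Fe", "Cl")


@dataclass(frozen=True)
class SpeciesSpec:
    """A chemical species.

    Parameters
    ----------
    name:
        Identifier, unique within a network.
    charge:
        Net charge in elementary charges.  For cystamine-derived species this
        includes the two protonated amino groups (cystamine itself is +2 below
        pH 8).
    diffusion_coefficient:
        Diffusion coefficient at 25 C in units of 1e-9 m^2/s (the customary
        tabulation unit).
    formula:
        Elemental composition, e.g. ``{"H": 2, "O": 2}`` for H2O2.  Used only
        for conservation checks.
    is_bulk:
        Background solute held at fixed concentration.
    """

    name: str
    charge: int
    diffusion_coefficient: float
    formula: dict = field(default_factory=dict)
    is_bulk: bool = False

    def __post_init__(self) -> None:
        if self.diffusion_coefficient < 0:
            raise ValueError(f"species {self.name}: diffusion coefficient < 0")
        bad = set(self.formula) - set(ELEMENTS)
        if bad:
            raise ValueError(f"species {self.name}: unknown elements {sorted(bad)}")

    @property
    def d_nm2_s(self) -> float:
        """Diffusion coefficient in nm^2/s."""
        return self.diffusion_coefficient * D_UNIT_TO_NM2_S

    def composition_vector(self) -> tuple:
        """(charge, counts of each tracked element), for balance arithmetic."""
        return (self.charge,) + tuple(self.formula.get(el, 0) for el in ELEMENTS)


# compositions of the implicit solvent participants
WATER = {"H": 2, "O": 1}
PROTON = {"H": 1}
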