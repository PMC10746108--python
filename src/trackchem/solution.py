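"""Bulk solution composition: the pseudo-first-order environment.

The standard aerated Fricke dosimeter is 1 mM FeSO4 in air-saturated
(~2.5e-4 M O2) aqueous 0.4 M H2SO4; cystamine is added as its dihydrochloride
at 1e-6 to 1 M.  Radiolytic products are trace relative to these backgrounds,
so every trace-bulk reaction is treated as pseudo-first-order.

Sulfuric-acid speciation: the first dissociation is complete; the second uses
the thermodynamic Ka2 = 1.2e-2, giving [H3O+] ~= 0.41 M and an ionic strength
of ~0.43 M for the standard composition (the nominal pH 0.46 of the classical
recipe corresponds to the proton *activity*).  The ionic strength can be
overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KA2_HSO4 = 1.2e-2  # second dissociation constant of H2SO4 at 25 C


def h2so4_speciation(c_acid: float) -> dict:
    """Equilibrium [H3O+], [HSO4-], [SO4 2-] of ``c_acid`` M sulfuric acid."""
    if c_acid == 0:
        return {"H3O+": 0.0, "HSO4-": 0.0, "SO4 2-": 0.0}
    c, ka = c_acid, KA2_HSO4
    # alpha = fraction of the second proton released
    alpha = (-(c + ka) + np.sqrt((c + ka) ** 2 + 4 * c * ka)) / (2 * c)
    return {
        "H3O+": c * (1 + alpha),
        "HSO4-": c * (1 - alpha),
        "SO4 2-": c * alpha,
    }


@dataclass
class BulkSolution:
    """Background solutes at fixed concentration (mol/L).

    ``concentrations`` maps species names used by the reaction network
    (``H3O+``, ``Fe2+``, ``O2``, ``RSSR``) to molarities.  ``ionic_strength``
    is computed from the composition unless overridden.
    """

    concentrations: dict = field(default_factory=dict)
    ionic_strength: float | None = None
    #: counter-ion bookkeeping for the ionic strength (not kinetic species)
    _ionic_strength_computed: float = field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name}")
        if self.ionic_strength is not None and self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")

    @classmethod
    def fricke(
        cls,
        cystamine: float = 0.0,
        *,
        fe2: float = 1.0e-3,
        o2: float = 2.5e-4,
        h2so4: float = 0.4,
        ionic_strength: float | None = None,
        count_cystamine_in_ionic_strength: bool = False,
    ) -> "BulkSolution":
        """Standard aerated Fricke composition, optionally with cystamine.

        By default the ionic strength counts the acid background and FeSO4
        only (I ~= 0.43 M): the Bronsted-Bjerrum/Debye-Huckel correction the
        rate constants are adjusted with is an extrapolation already at this
        I and loses meaning entirely at the multi-molar values reached if a
        molar cystamine salt is included.  Set
        ``count_cystamine_in_ionic_strength=True`` (dihydrochloride, z = +2
        plus two chlorides, dI = 3c) or override ``ionic_strength`` to
        explore that regime.
        """
        if cystamine < 0:
            raise ValueError("cystamine concentration must be >= 0")
        spec = h2so4_speciation(h2so4)
        conc = {
            "H3O+": spec["H3O+"],
            "Fe2+": fe2,
            "O2": o2,
            "RSSR": cystamine,
        }
        if ionic_strength is None:
            i_acid = 0.5 * (
                spec["H3O+"] + spec["HSO4-"] + 4.0 * spec["SO4 2-"]
            )
            i_fe = 0.5 * (4.0 * fe2 + 4.0 * fe2)
            ionic_strength = i_acid + i_fe
            if count_cystamine_in_ionic_strength:
                ionic_strength += 0.5 * (4.0 * cystamine + 2.0 * cystamine)
        return cls(concentrations=conc, ionic_strength=ionic_strength)

    def conc(self, name: str) -> float:
        return self.concentrations.get(name, 0.0)

    @property
    def ph(self) -> float:
        """-log10 of the proton concentration (not activity)."""
        h = self.conc("H3O+")
        return float("inf") if h <= 0 else -float(np.log10(h))
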