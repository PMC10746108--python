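"""Reaction network: species, reactions, rate-constant arithmetic.

The default scheme (loaded from ``data/default_scheme.toml``) combines

* the four ferrous-oxidation reactions of the aerated Fricke dosimeter,
* the twelve cystamine reactions most important for ferric-ion production,
  plus the standard thiyl self-termination,
* a standard compiled pure-water radiolysis set (Elliot/Buxton-style 25 C
  constants), and
* the two oxygen-atom reactions that matter when double ionization of water
  is enabled.

Rate constants are 25 C infinite-dilution values; ion-ion channels are
corrected for ionic strength with a Bronsted-Bjerrum / extended Debye-Huckel
factor (:func:`correct_for_ionic_strength`).
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .species import ELEMENTS, SpeciesSpec
from .units import k_molar_to_per_molecule

KINETIC_CLASSES = (
    "fully-diffusion-controlled",
    "partially-diffusion-controlled",
    "bulk-pseudo-first-order",
)

#: encounter-radius cap (nm) applied to ionic-strength-corrected rate
#: constants; the Davies-type factor extrapolated to molar ionic strengths
#: can otherwise exceed diffusion control.
DEFAULT_RADIUS_CAP_NM = 1.0


class SchemeError(ValueError):
    """Raised when a reaction scheme fails validation."""


@dataclass(frozen=True)
class Reaction:
    """A one- or two-reactant channel.

    ``implicit_hplus`` counts protons taken from (positive) or released to
    (negative) the acid background, the "(+ H+)" of the printed scheme; water
    is always allowed implicitly.
    """

    id: int
    reactants: tuple
    products: tuple
    k25: float
    kinetic_class: str
    implicit_hplus: int = 0
    ionic_strength_exempt: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.k25 <= 0:
            raise SchemeError(f"reaction {self.id}: k25 must be > 0")
        if self.kinetic_class not in KINETIC_CLASSES:
            raise SchemeError(
                f"reaction {self.id}: unknown kinetic class {self.kinetic_class!r}"
            )
        if not 1 <= len(self.reactants) <= 2:
            raise SchemeError(f"reaction {self.id}: needs 1 or 2 reactants")

    @property
    def is_bimolecular(self) -> bool:
        return len(self.reactants) == 2


@dataclass
class ReactionNetwork:
    """A validated set of species and reactions."""

    species: dict = field(default_factory=dict)  # name -> SpeciesSpec
    reactions: list = field(default_factory=list)
    equilibria: dict = field(default_factory=dict)  # "A/HA" -> pKa

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------

    def spec(self, name: str) -> SpeciesSpec:
        try:
            return self.species[name]
        except KeyError:
            raise SchemeError(f"unknown species {name!r}") from None

    def reaction(self, rid: int) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction with id {rid}")

    def reactions_of(self, name: str) -> list:
        """All reactions consuming ``name``."""
        return [r for r in self.reactions if name in r.reactants]

    def producers_of(self, name: str) -> list:
        return [r for r in self.reactions if name in r.products]

    def pair_reactions(self) -> list:
        """Trace-trace channels sampled as diffusive pair encounters."""
        return [
            r
            for r in self.reactions
            if r.is_bimolecular
            and not any(self.spec(s).is_bulk for s in r.reactants)
        ]

    def bulk_reactions(self) -> list:
        """Channels with one bulk co-reactant (pseudo-first-order)."""
        return [
            r
            for r in self.reactions
            if r.is_bimolecular
            and sum(self.spec(s).is_bulk for s in r.reactants) == 1
        ]

    def trace_reactant_of(self, r: Reaction) -> str:
        """The non-bulk reactant of a pseudo-first-order channel."""
        trace = [s for s in r.reactants if not self.spec(s).is_bulk]
        if len(trace) != 1:
            raise SchemeError(f"reaction {r.id} is not pseudo-first-order")
        return trace[0]

    def bulk_reactant_of(self, r: Reaction) -> str:
        bulk = [s for s in r.reactants if self.spec(s).is_bulk]
        if len(bulk) != 1:
            raise SchemeError(f"reaction {r.id} has no unique bulk reactant")
        return bulk[0]

    def charge_product(self, r: Reaction) -> int:
        if not r.is_bimolecular:
            return 0
        a, b = (self.spec(s).charge for s in r.reactants)
        return a * b

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        seen = set()
        for r in self.reactions:
            if r.id in seen:
                raise SchemeError(f"duplicate reaction id {r.id}")
            seen.add(r.id)
            for name in r.reactants + r.products:
                if name not in self.species:
                    raise SchemeError(
                        f"reaction {r.id}: undeclared species {name!r}"
                    )
            self._check_balance(r)
        for r in self.reactions:
            if "Fe3+" in r.reactants:
                raise SchemeError(f"reaction {r.id}: Fe3+ must not be a reactant")

    def _check_balance(self, r: Reaction) -> None:
        """Element and charge balance, allowing implicit H2O and declared H+."""
        charge = r.implicit_hplus
        elems = {el: 0 for el in ELEMENTS}
        elems["H"] += r.implicit_hplus
        for name in r.reactants:
            sp = self.spec(name)
            charge += sp.charge
            for el, n in sp.formula.items():
                elems[el] += n
        for name in r.products:
            sp = self.spec(name)
            charge -= sp.charge
            for el, n in sp.formula.items():
                elems[el] -= n
        # residual must be an integer number of water molecules
        ok = (
            charge == 0
            and all(elems[el] == 0 for el in ELEMENTS if el not in ("H", "O"))
            and elems["H"] == 2 * elems["O"]
        )
        if not ok:
            raise SchemeError(
                f"reaction {r.id} is not balanced "
                f"(residual charge {charge}, elements {elems})"
            )

    # -- export ----------------------------------------------------------

    def to_json(self) -> str:
        """Provenance dump of the resolved scheme."""
        doc = {
            "species": [
                {
                    "name": s.name,
                    "charge": s.charge,
                    "d": s.diffusion_coefficient,
                    "formula": s.formula,
                    "is_bulk": s.is_bulk,
                }
                for s in self.species.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "k25": r.k25,
                    "kinetic_class": r.kinetic_class,
                    "implicit_hplus": r.implicit_hplus,
                    "ionic_strength_exempt": r.ionic_strength_exempt,
                }
                for r in self.reactions
            ],
            "equilibria": self.equilibria,
        }
        return json.dumps(doc, indent=1, sort_keys=True)


# ---------------------------------------------------------------- scheme I/O


def _parse_species(entry: dict) -> SpeciesSpec:
    return SpeciesSpec(
        name=entry["name"],
        charge=int(entry.get("charge", 0)),
        diffusion_coefficient=float(entry["d"]),
        formula={k: int(v) for k, v in entry.get("formula", {}).items()},
        is_bulk=bool(entry.get("is_bulk", False)),
    )


def _parse_reaction(entry: dict) -> Reaction:
    return Reaction(
        id=int(entry["id"]),
        reactants=tuple(entry["reactants"]),
        products=tuple(entry.get("products", [])),
        k25=float(entry["k25"]),
        kinetic_class=entry.get("kinetic_class", "partially-diffusion-controlled"),
        implicit_hplus=int(entry.get("implicit_hplus", 0)),
        ionic_strength_exempt=bool(entry.get("ionic_strength_exempt", False)),
        note=entry.get("note", ""),
    )


def load_scheme(config_source=None) -> ReactionNetwork:
    """Load and validate a reaction scheme.

    ``config_source`` may be ``None`` (packaged defaults), a path to a TOML
    file, a TOML string, or an already-parsed dict.  A user document with
    ``include_default = true`` extends the default scheme: its species and
    reactions are added, entries with an existing id/name replace the default
    ones.
    """
    if config_source is None:
        doc = tomllib.loads(
            resources.files("trackchem.data")
            .joinpath("default_scheme.toml")
            .read_text()
        )
    elif isinstance(config_source, dict):
        doc = config_source
    else:
        text = None
        p = Path(str(config_source))
        try:
            if p.is_file():
                text = p.read_text()
        except OSError:
            pass
        if text is None:
            text = str(config_source)
        try:
            doc = tomllib.loads(text)
        except tomllib.TOMLDecodeError as exc:
            raise SchemeError(f"scheme config does not parse: {exc}") from exc

    if doc.get("include_default"):
        base = load_scheme(None)
        species = dict(base.species)
        reactions = {r.id: r for r in base.reactions}
        equilibria = dict(base.equilibria)
    else:
        species, reactions, equilibria = {}, {}, {}

    for entry in doc.get("species", []):
        sp = _parse_species(entry)
        species[sp.name] = sp
    for entry in doc.get("reactions", []):
        r = _parse_reaction(entry)
        reactions[r.id] = r
    equilibria.update(doc.get("equilibria", {}))

    return ReactionNetwork(
        species=species,
        reactions=sorted(reactions.values(), key=lambda r: r.id),
        equilibria=equilibria,
    )


# ----------------------------------------------------------- rate arithmetic


def correct_for_ionic_strength(
    k25: float,
    z_a: int,
    z_b: int,
    ionic_strength: float,
    *,
    coeff: float = 1.02,
    davies_term: float = 0.0,
) -> float:
    """Bronsted-Bjerrum ionic-strength correction of a bimolecular k.

    ``k = k25 * 10 ** (coeff * z_a * z_b * (sqrt(I)/(1+sqrt(I)) - davies_term * I))``

    The default is the extended Debye-Huckel form (``davies_term = 0``); set
    ``davies_term = 0.3`` for the Davies equation.  Identity when the charge
    product is zero or I = 0.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    zz = z_a * z_b
    if zz == 0 or ionic_strength == 0:
        return k25
    s = np.sqrt(ionic_strength)
    factor = 10.0 ** (coeff * zz * (s / (1.0 + s) - davies_term * ionic_strength))
    return k25 * factor


def diffusion_reaction_radius(k25: float, d_mutual_nm2_s: float) -> float:
    """Effective encounter radius (nm) reproducing ``k25``.

    ``R = k' / (4 pi D)`` with ``k'`` the per-molecule rate (nm^3/s) and D the
    mutual diffusion coefficient (nm^2/s).  Used for every diffusive pair
    channel: fully diffusion-controlled reactions get their contact radius,
    partially diffusion-controlled ones the (smaller) Collins-Kimball-style
    effective radius that reproduces the observed rate constant.
    """
    if k25 <= 0 or d_mutual_nm2_s <= 0:
        raise ValueError("k25 and D_mutual must be > 0")
    return k_molar_to_per_molecule(k25) / (4.0 * np.pi * d_mutual_nm2_s)


def diffusion_limited_k(d_mutual_nm2_s: float, radius_nm: float) -> float:
    """Rate constant (M^-1 s^-1) of a fully diffusion-controlled reaction."""
    return 4.0 * np.pi * d_mutual_nm2_s * radius_nm / k_molar_to_per_molecule(1.0)


def effective_k(
    network: ReactionNetwork,
    r: Reaction,
    ionic_strength: float,
    *,
    radius_cap_nm: float = DEFAULT_RADIUS_CAP_NM,
    davies_term: float = 0.0,
) -> float:
    """Ionic-strength-corrected rate constant of ``r``, capped at diffusion
    control for an encounter radius of ``radius_cap_nm``."""
    if r.ionic_strength_exempt or not r.is_bimolecular:
        return r.k25
    a, b = (network.spec(s) for s in r.reactants)
    k = correct_for_ionic_strength(
        r.k25, a.charge, b.charge, ionic_strength, davies_term=davies_term
    )
    if radius_cap_nm is not None:
        d_mut = a.d_nm2_s + b.d_nm2_s
        k_cap = diffusion_limited_k(d_mut, radius_cap_nm)
        # only cap upward corrections; a k25 already above the nominal cap
        # (fast proton-transfer channels) is left untouched
        if k > r.k25:
            k = min(k, max(k_cap, r.k25))
    return k


# ------------------------------------------------------ scavenging arithmetic


def scavenging_time(k: float, c: float) -> float:
    """Inverse scavenging power 1/(k c) in seconds."""
    if k <= 0 or c <= 0:
        raise ValueError("k and c must be > 0")
    return 1.0 / (k * c)


def branching_fractions(channels: Sequence) -> np.ndarray:
    """Competition fractions ``k_i c_i / sum_j k_j c_j``.

    ``channels`` is a sequence of (k, c) pairs; all products must be >= 0 and
    at least one positive.
    """
    rates = np.array([k * c for k, c in channels], dtype=float)
    if len(rates) == 0:
        raise ValueError("at least one channel required")
    if np.any(rates < 0):
        raise ValueError("negative scavenging power")
    total = rates.sum()
    if total <= 0:
        raise ValueError("all channels have zero rate")
    return rates / total
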