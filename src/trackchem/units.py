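"""Unit conversions used throughout the package.

Internal conventions:

* lengths in nm, times in s, diffusion coefficients in nm^2/s,
* bimolecular rate constants are stored as given in the literature
  (M^-1 s^-1) and converted to per-molecule units (nm^3/s) only where the
  IRT engine needs an encounter radius,
* radiation chemical yields (G values) in molecules per 100 eV.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23  # 1/mol

#: nm^3 per litre
NM3_PER_L = 1.0e24

#: conversion factor: k [M^-1 s^-1] -> k [nm^3 / (molecule s)]
K_MOLAR_TO_NM3 = NM3_PER_L / AVOGADRO  # ~1.6606

#: 1 molecule / 100 eV expressed in umol/J
GVALUE_UMOL_PER_J = 0.10364

#: diffusion coefficient, 1e-9 m^2/s -> nm^2/s
D_UNIT_TO_NM2_S = 1.0e9


def k_molar_to_per_molecule(k: float) -> float:
    """Convert a bimolecular rate constant from M^-1 s^-1 to nm^3/s."""
    return k * K_MOLAR_TO_NM3


def convert_gvalue_units(g: float) -> float:
    """Convert a G value from molecules per 100 eV to umol/J."""
    return g * GVALUE_UMOL_PER_J
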