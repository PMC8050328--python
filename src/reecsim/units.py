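"""Unit conversions for the package's internal unit system.

Everything inside the package is expressed in **µm, s, µM, cells**.  The
published parameter tables for chamber transport models mix unit systems
(molecules per cell per second, cells per cm², mM, µL), and silent mixing is
the main correctness risk, so every conversion goes through the factors
defined here.

Factors
-------
- Avogadro constant: 6.02214076e23 molecules/mol (exact, SI 2019).
- 1 µM = 1e-6 mol/L = 1e-6 mol / 1e15 µm³ = 1e-21 mol/µm³.
- 1 cell/cm² = 1e-8 cells/µm².
- 1 µL = 1e9 µm³.
- 1 mm = 1e3 µm.
"""

AVOGADRO = 6.02214076e23
"""Molecules per mole."""

MOL_PER_UM3_PER_UM_CONC = 1e-21
"""mol/µm³ per µM of concentration."""

CELLS_PER_UM2_PER_CELLS_PER_CM2 = 1e-8
"""cells/µm² per (cells/cm²)."""

UL_PER_UM3 = 1e-9
"""µL per µm³."""

UM_PER_MM = 1e3
"""µm per mm."""


def uM_to_mol_per_um3(c_uM: float) -> float:
    """Concentration in µM -> mol/µm³."""
    return c_uM * MOL_PER_UM3_PER_UM_CONC


def mol_per_um3_to_uM(c: float) -> float:
    """Concentration in mol/µm³ -> µM."""
    return c / MOL_PER_UM3_PER_UM_CONC


def molecules_per_s_to_mol_per_s(rate: float) -> float:
    """Molecular rate (molecules/s) -> molar rate (mol/s)."""
    return rate / AVOGADRO


def cells_per_cm2_to_per_um2(sigma: float) -> float:
    """Areal cell density in cells/cm² -> cells/µm²."""
    return sigma * CELLS_PER_UM2_PER_CELLS_PER_CM2


def um3_to_uL(v: float) -> float:
    """Volume in µm³ -> µL."""
    return v * UL_PER_UM3
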