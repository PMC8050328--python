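"""Transport parameters and closed-form diffusion-consumption quantities.

A restricted exchange environment chamber (REEC) is a shallow (~100-140 µm)
chamber placed over a cell monolayer.  A single small aperture in its top
coverslip is the only route by which oxygen and nutrients reach the cells, so
the monolayer's own consumption carves radial concentration gradients into the
chamber.  This module holds the parameter containers for that system and the
quantities that have closed forms:

- the per-cell rate constant ``k`` derived from a maximum per-cell consumption
  rate ``A_max`` via ``A_max = k · C_bulk``;
- the characteristic diffusion-consumption length ``λ = sqrt(D / (n·k))``;
- the saturating volumetric consumption term ``n·k·f(C)`` with
  ``f(C) = C_bulk · C / (C + K)`` (half-saturation ``K`` defaults to
  ``C_bulk``, reproducing the saturating form used to model the chamber);
- a one-dimensional Fick's-law column model for the oxygen drop across the
  media column above a consuming monolayer;
- the chamber interior volume.

Internally everything is in µm / s / µM / cells; the constructors accept the
conventional units the quantities are usually quoted in (cells/cm² for areal
density, molecules·cell⁻¹·s⁻¹ for ``A_max``) and convert through
:mod:`reecsim.units`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from . import units
from .errors import InfiniteLengthError, InvalidParameterError, InvalidStateError

__all__ = [
    "ChamberGeometry",
    "TransportParams",
    "ConsumerField",
    "ColumnSpec",
    "per_cell_rate",
    "characteristic_length",
    "consumption_term",
    "column_model",
    "chamber_volume",
    "OXYGEN",
    "GLUCOSE",
    "DEFAULT_CONSUMERS",
]


@dataclass(frozen=True)
class ChamberGeometry:
    """Annular chamber geometry, all lengths in µm.

    ``r_inner`` is the radius of the aperture (the oxygen/nutrient source),
    ``r_outer`` the inner radius of the chamber wall.  ``height`` defaults to
    the 100 µm used for the dynamic model; the as-built mean height including
    the epoxy layer (138.4 µm) is used for volume checks.
    """

    r_inner: float = 350.0
    r_outer: float = 6000.0
    height: float = 100.0
    hole_diameter: float = 740.1

    def __post_init__(self) -> None:
        if not (0 < self.r_inner < self.r_outer):
            raise InvalidParameterError(
                f"require 0 < r_inner < r_outer, got {self.r_inner}, {self.r_outer}"
            )
        if self.height <= 0:
            raise InvalidParameterError(f"height must be > 0, got {self.height}")
        if self.hole_diameter <= 0:
            raise InvalidParameterError("hole_diameter must be > 0")


@dataclass(frozen=True)
class TransportParams:
    """One molecular species' transport/consumption parameters.

    Parameters
    ----------
    name
        Species label, e.g. ``"oxygen"``.
    D
        Diffusivity in media, µm²/s.
    A_max
        Maximum per-cell consumption rate, molecules·cell⁻¹·s⁻¹.
    C_bulk
        Concentration at the source boundary (well-mixed upper compartment),
        µM.
    half_saturation
        Half-saturation constant ``K`` of the consumption law, µM.  ``None``
        (the default) means ``K = C_bulk``.
    """

    name: str
    D: float
    A_max: float
    C_bulk: float
    half_saturation: float | None = None

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise InvalidParameterError(f"D must be > 0, got {self.D}")
        if self.A_max < 0:
            raise InvalidParameterError(f"A_max must be >= 0, got {self.A_max}")
        if self.C_bulk <= 0:
            raise InvalidParameterError(f"C_bulk must be > 0, got {self.C_bulk}")
        if self.half_saturation is None:
            object.__setattr__(self, "half_saturation", float(self.C_bulk))
        elif self.half_saturation <= 0:
            raise InvalidParameterError(
                f"half_saturation must be > 0, got {self.half_saturation}"
            )

    def with_amax(self, A_max: float) -> "TransportParams":
        """Copy with a different maximum per-cell consumption rate."""
        return replace(self, A_max=A_max)


@dataclass(frozen=True)
class ConsumerField:
    """Uniform density of consuming cells in the chamber.

    ``areal_density`` is in cells/cm² (the unit cell plating densities are
    quoted in); ``height`` is the chamber height in µm over which the
    monolayer's consumption is smeared to give a volumetric density.
    """

    areal_density: float = 2.0e5
    height: float = 100.0

    def __post_init__(self) -> None:
        if self.areal_density < 0:
            raise InvalidParameterError("areal_density must be >= 0")
        if self.height <= 0:
            raise InvalidParameterError("height must be > 0")

    @property
    def areal_density_per_um2(self) -> float:
        """Areal density in cells/µm²."""
        return units.cells_per_cm2_to_per_um2(self.areal_density)

    @property
    def volumetric_density(self) -> float:
        """Volumetric density n in cells/µm³ (areal density / height)."""
        return self.areal_density_per_um2 / self.height

    def scaled(self, factor: float) -> "ConsumerField":
        """Copy with the areal density multiplied by ``factor``."""
        return replace(self, areal_density=self.areal_density * factor)


@dataclass(frozen=True)
class ColumnSpec:
    """Inputs to the Fick's-law media-column model.

    The column spans the chamber height plus the top coverslip thickness;
    its top is held at the fully oxygenated concentration ``C_top`` and the
    consuming monolayer sits at the bottom.
    """

    consumers: ConsumerField
    species: TransportParams
    column_height: float = 250.0
    C_top: float = 178.0

    def __post_init__(self) -> None:
        if self.column_height <= 0:
            raise InvalidParameterError("column_height must be > 0")
        if self.C_top <= 0:
            raise InvalidParameterError("C_top must be > 0")


def per_cell_rate(species: TransportParams) -> float:
    """Per-cell rate constant ``k = A_max / C_bulk`` in µm³·cell⁻¹·s⁻¹.

    ``A_max`` (molecules·cell⁻¹·s⁻¹) is converted to mol/s via Avogadro's
    number and ``C_bulk`` (µM) to mol/µm³, so the ratio has units of volume
    cleared per cell per second.
    """
    a_mol = units.molecules_per_s_to_mol_per_s(species.A_max)
    c_mol = units.uM_to_mol_per_um3(species.C_bulk)
    return a_mol / c_mol


def characteristic_length(species: TransportParams, consumers: ConsumerField) -> float:
    """Characteristic diffusion-consumption length ``λ = sqrt(D/(n·k))`` in µm.

    Raises
    ------
    InfiniteLengthError
        If ``n·k == 0`` (no consumers or no consumption), for which λ is
        infinite.
    """
    n = consumers.volumetric_density
    k = per_cell_rate(species)
    if n * k == 0:
        raise InfiniteLengthError(
            "characteristic length is infinite when n*k == 0 "
            f"(n={n}, k={k})"
        )
    return math.sqrt(species.D / (n * k))


def consumption_term(C, species: TransportParams, consumers: ConsumerField):
    """Volumetric consumption rate ``n·k·f(C)`` in µM/s.

    ``f(C) = C_bulk · C / (C + K)`` with half-saturation ``K``; the value is
    continuous at C = 0 (rate 0) and saturates at ``n·k·C_bulk``, which equals
    the per-volume maximum ``n·A_max`` after unit conversion.  Accepts scalars
    or numpy arrays.
    """
    import numpy as np

    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise InvalidStateError("concentration must be >= 0")
    n = consumers.volumetric_density
    k = per_cell_rate(species)
    K = species.half_saturation
    with np.errstate(invalid="ignore"):
        f = np.where(C > 0, species.C_bulk * C / (C + K), 0.0)
    out = n * k * f
    return float(out) if out.ndim == 0 else out


def column_model(spec: ColumnSpec) -> float:
    """Steady O₂ concentration at the cell layer of a media column, in µM.

    The consuming monolayer is confined to the bottom of a column of height
    ``L`` whose top is held at ``C_top``.  At steady state the diffusive flux
    through the column equals the monolayer uptake ``J = σ·A_max`` and the
    profile is linear, so ``C_cell = C_top − J·L/D``.  A negative closed-form
    value (consumption exceeding what diffusion can supply) is clamped to 0
    with a warning.
    """
    sp = spec.species
    sigma = spec.consumers.areal_density_per_um2  # cells/µm²
    j_mol = sigma * units.molecules_per_s_to_mol_per_s(sp.A_max)  # mol µm⁻² s⁻¹
    drop = units.mol_per_um3_to_uM(j_mol * spec.column_height / sp.D)
    c_cell = spec.C_top - drop
    if c_cell < 0:
        warnings.warn(
            "column model is consumption-saturated: naive cell-layer "
            f"concentration {c_cell:.3g} µM < 0, clamping to 0",
            stacklevel=2,
        )
        return 0.0
    return c_cell


def chamber_volume(geom: ChamberGeometry) -> float:
    """Interior chamber volume (cylinder of radius r_outer × height), in µL."""
    return units.um3_to_uL(math.pi * geom.r_outer**2 * geom.height)


# Default parameter sets for the chamber / 4T1 system.  Oxygen's C_bulk is the
# 171 µM present at the aperture after the Fick's-law column correction; the
# fully oxygenated media value 178 µM enters only as ColumnSpec.C_top.
OXYGEN = TransportParams(name="oxygen", D=3370.0, A_max=2.98e7, C_bulk=171.0)
GLUCOSE = TransportParams(name="glucose", D=616.0, A_max=6.47e7, C_bulk=25000.0)
DEFAULT_CONSUMERS = ConsumerField(areal_density=2.0e5, height=100.0)
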