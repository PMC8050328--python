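"""Declarative run configuration (TOML) for the whole pipeline.

One flat key-value file with sections describes geometry, species transport
parameters, consumer density, solver settings, profiling settings and the
synthetic-data generator.  The schema is strict: unknown sections or keys are
rejected with an error naming them, and every key name carries its unit.  A
bundled default file (``reecsim/data/defaults.toml``) holds the chamber / 4T1
parameter set.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ConfigError, InvalidParameterError
from .simulator import SimulationConfig
from .synthdata import IntensityModel
from .transport import ChamberGeometry, ConsumerField, TransportParams

__all__ = ["ProfilingSettings", "SynthSettings", "RunConfig", "load_config", "default_config"]

_SCHEMA: dict[str, set[str]] = {
    "geometry": {"r_inner_um", "r_outer_um", "height_um", "hole_diameter_um"},
    "species": {
        "D_um2_s",
        "A_max_molecules_cell_s",
        "C_bulk_uM",
        "half_saturation_uM",
        "C_top_uM",
    },
    "consumers": {"areal_density_cells_cm2", "height_um"},
    "column": {"column_height_um"},
    "simulation": {
        "t_end_s",
        "inspection_interval_s",
        "rms_tol",
        "dt_s",
        "grid_spacing_um",
        "linear_consumption",
    },
    "profiling": {
        "bin_width_um",
        "smoothing_window",
        "front_fraction",
        "intensity_mode",
        "distance_mode",
        "max_radius_um",
    },
    "synth": {
        "density_cells_cm2",
        "response",
        "I_max",
        "noise_sigma",
        "background",
        "C_thr_uM",
        "sigmoid_width_uM",
    },
}


@dataclass(frozen=True)
class ProfilingSettings:
    """Binning / smoothing / front-detection settings."""

    bin_width: float = 50.0
    smoothing_window: int = 5
    front_fraction: float = 0.9
    intensity_mode: str = "first_point"
    distance_mode: str = "absolute"
    max_radius: float | None = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigError("bin_width_um must be > 0")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ConfigError("smoothing_window must be odd and >= 1")
        if not (0 < self.front_fraction <= 1):
            raise ConfigError("front_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SynthSettings:
    """Synthetic-data generator settings (density + reporter response)."""

    density_cells_cm2: float = 2.0e5
    response: str = "hypoxia_linear"
    I_max: float = 1000.0
    noise_sigma: float = 0.2
    background: float = 0.0
    C_thr_uM: float = 44.5
    sigmoid_width_uM: float = 10.0

    def intensity_model(self, C_ref: float) -> IntensityModel:
        return IntensityModel(
            kind=self.response,
            I_max=self.I_max,
            C_ref=C_ref,
            C_thr=self.C_thr_uM,
            width=self.sigmoid_width_uM,
            background=self.background,
            noise_sigma=self.noise_sigma,
        )


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full simulate → synthesize → profile run."""

    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    species: dict[str, TransportParams] = field(default_factory=dict)
    c_top: dict[str, float] = field(default_factory=dict)
    consumers: ConsumerField = field(default_factory=ConsumerField)
    column_height: float = 250.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    profiling: ProfilingSettings = field(default_factory=ProfilingSettings)
    synth: SynthSettings = field(default_factory=SynthSettings)

    def species_or_fail(self, name: str) -> TransportParams:
        try:
            return self.species[name]
        except KeyError:
            raise ConfigError(
                f"species {name!r} not in config (have {sorted(self.species)})"
            ) from None


def _check_keys(section: str, mapping: dict, allowed: set[str]) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")


def _parse(raw: dict) -> RunConfig:
    top_unknown = set(raw) - set(_SCHEMA)
    if top_unknown:
        raise ConfigError(f"unknown section(s): {sorted(top_unknown)}")

    geo_raw = raw.get("geometry", {})
    _check_keys("geometry", geo_raw, _SCHEMA["geometry"])
    try:
        geometry = ChamberGeometry(
            r_inner=geo_raw.get("r_inner_um", 350.0),
            r_outer=geo_raw.get("r_outer_um", 6000.0),
            height=geo_raw.get("height_um", 100.0),
            hole_diameter=geo_raw.get("hole_diameter_um", 740.1),
        )
    except InvalidParameterError as exc:
        raise ConfigError(f"[geometry]: {exc}") from exc

    species: dict[str, TransportParams] = {}
    c_top: dict[str, float] = {}
    for name, sp_raw in raw.get("species", {}).items():
        if not isinstance(sp_raw, dict):
            raise ConfigError(f"[species.{name}] must be a table")
        _check_keys(f"species.{name}", sp_raw, _SCHEMA["species"])
        for key in ("D_um2_s", "A_max_molecules_cell_s", "C_bulk_uM"):
            if key not in sp_raw:
                raise ConfigError(f"[species.{name}] missing required key {key!r}")
        try:
            species[name] = TransportParams(
                name=name,
                D=sp_raw["D_um2_s"],
                A_max=sp_raw["A_max_molecules_cell_s"],
                C_bulk=sp_raw["C_bulk_uM"],
                half_saturation=sp_raw.get("half_saturation_uM"),
            )
        except InvalidParameterError as exc:
            # surface the offending field name for CLI diagnostics
            raise ConfigError(f"[species.{name}]: {exc}") from exc
        if "C_top_uM" in sp_raw:
            c_top[name] = float(sp_raw["C_top_uM"])

    cons_raw = raw.get("consumers", {})
    _check_keys("consumers", cons_raw, _SCHEMA["consumers"])
    try:
        consumers = ConsumerField(
            areal_density=cons_raw.get("areal_density_cells_cm2", 2.0e5),
            height=cons_raw.get("height_um", 100.0),
        )
    except InvalidParameterError as exc:
        raise ConfigError(f"[consumers]: {exc}") from exc

    col_raw = raw.get("column", {})
    _check_keys("column", col_raw, _SCHEMA["column"])
    column_height = float(col_raw.get("column_height_um", 250.0))

    sim_raw = raw.get("simulation", {})
    _check_keys("simulation", sim_raw, _SCHEMA["simulation"])
    try:
        simulation = SimulationConfig(
            t_end=sim_raw.get("t_end_s", 172800.0),
            inspection_interval=sim_raw.get("inspection_interval_s", 60.0),
            rms_tol=sim_raw.get("rms_tol", 1e-3),
            dt=sim_raw.get("dt_s"),
            grid_spacing=sim_raw.get("grid_spacing_um", 10.0),
            linear_consumption=sim_raw.get("linear_consumption", False),
        )
    except InvalidParameterError as exc:
        raise ConfigError(f"[simulation]: {exc}") from exc

    prof_raw = raw.get("profiling", {})
    _check_keys("profiling", prof_raw, _SCHEMA["profiling"])
    profiling = ProfilingSettings(
        bin_width=prof_raw.get("bin_width_um", 50.0),
        smoothing_window=prof_raw.get("smoothing_window", 5),
        front_fraction=prof_raw.get("front_fraction", 0.9),
        intensity_mode=prof_raw.get("intensity_mode", "first_point"),
        distance_mode=prof_raw.get("distance_mode", "absolute"),
        max_radius=prof_raw.get("max_radius_um"),
    )

    synth_raw = raw.get("synth", {})
    _check_keys("synth", synth_raw, _SCHEMA["synth"])
    synth = SynthSettings(
        density_cells_cm2=synth_raw.get("density_cells_cm2", 2.0e5),
        response=synth_raw.get("response", "hypoxia_linear"),
        I_max=synth_raw.get("I_max", 1000.0),
        noise_sigma=synth_raw.get("noise_sigma", 0.2),
        background=synth_raw.get("background", 0.0),
        C_thr_uM=synth_raw.get("C_thr_uM", 44.5),
        sigmoid_width_uM=synth_raw.get("sigmoid_width_uM", 10.0),
    )

    return RunConfig(
        geometry=geometry,
        species=species,
        c_top=c_top,
        consumers=consumers,
        column_height=column_height,
        simulation=simulation,
        profiling=profiling,
        synth=synth,
    )


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a TOML run configuration."""
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return _parse(raw)


def default_config() -> RunConfig:
    """The bundled chamber / 4T1 default parameter set."""
    data = resources.files("reecsim.data").joinpath("defaults.toml").read_bytes()
    return _parse(tomllib.loads(data.decode()))


def default_config_text() -> str:
    """Raw text of the bundled default configuration file."""
    return resources.files("reecsim.data").joinpath("defaults.toml").read_text()
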