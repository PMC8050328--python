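"""Seeded synthetic cell tables and images with chamber-like radial structure.

No public dataset of segmented chamber micrographs exists, so the profiling
pipeline is exercised on synthetic data whose radial structure comes from the
simulator plus explicit noise models:

- cell positions are drawn from an inhomogeneous spatial Poisson process with
  a radius-dependent areal density (uniform monolayers, or disk-shaped
  profiles with a logistic edge emulating the cell disks that form around the
  aperture over days);
- per-cell reporter intensities follow a monotone response to the local
  simulated concentration — by default linear in (1 − C/C_ref) for a hypoxia
  reporter whose signal rises as oxygen falls, with a sigmoidal
  (threshold-like) option — multiplied by log-normal noise;
- raster images are sums of Gaussian spots with optional multiplicative
  checkerboard modulation emulating the tile-stitching artifact of mosaicked
  widefield acquisitions, and optional Poisson shot noise.

All randomness flows from one explicit integer seed; each operation derives
its own substream deterministically (via :func:`numpy.random.SeedSequence`
with a per-operation tag), so identical seeds reproduce outputs
byte-for-byte.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .profiling import CellTable
from .simulator import ConcentrationProfile
from .transport import ChamberGeometry

__all__ = [
    "DensityProfile",
    "IntensityModel",
    "DiskSeriesParams",
    "sample_cells",
    "assign_intensities",
    "make_disk_series",
    "render_image",
]

# per-operation tags for deterministic substreams off the user's seed
_TAG_SAMPLE = 101
_TAG_ASSIGN = 102
_TAG_RENDER = 103


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


@dataclass(frozen=True)
class DensityProfile:
    """Expected areal cell density (cells/µm²) as a function of radius (µm)."""

    r: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        d = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "density", d)
        if r.ndim != 1 or r.size < 2 or np.any(np.diff(r) <= 0):
            raise InvalidParameterError("r must be increasing with >= 2 points")
        if d.shape != r.shape or np.any(~np.isfinite(d)) or np.any(d < 0):
            raise InvalidParameterError("density must be finite and >= 0")

    @classmethod
    def uniform(
        cls, density: float, r_min: float = 0.0, r_max: float = 6000.0
    ) -> "DensityProfile":
        return cls(np.array([r_min, r_max]), np.array([density, density]))

    @classmethod
    def disk(
        cls,
        density: float,
        disk_radius: float,
        edge_width: float = 100.0,
        r_min: float = 0.0,
        r_max: float = 6000.0,
        n_points: int = 512,
    ) -> "DensityProfile":
        """Disk-shaped profile: full density inside, logistic fall at the edge."""
        r = np.linspace(r_min, r_max, n_points)
        d = density / (1.0 + np.exp((r - disk_radius) / edge_width))
        return cls(r, d)

    def at(self, r: np.ndarray) -> np.ndarray:
        return np.interp(r, self.r, self.density)


@dataclass(frozen=True)
class IntensityModel:
    """Monotone map from concentration to expected per-cell intensity.

    ``kind='hypoxia_linear'``: I = background + I_max · max(0, 1 − C/C_ref)
    (signal rises as the species is depleted, like a fluorogenic hypoxia
    reporter).  ``kind='direct'``: I = background + gain · C.
    ``kind='hypoxia_sigmoid'``: I = background + I_max / (1 + exp((C − C_thr)/width)),
    a thresholded reporter activating below ``C_thr``.
    Per-cell multiplicative noise is log-normal: I · exp(ε), ε ~ N(0, σ²).
    """

    kind: str = "hypoxia_linear"
    I_max: float = 1000.0
    C_ref: float = 171.0
    gain: float = 1.0
    C_thr: float = 44.5
    width: float = 10.0
    background: float = 0.0
    noise_sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in ("hypoxia_linear", "direct", "hypoxia_sigmoid"):
            raise InvalidParameterError(f"unknown response kind {self.kind!r}")
        if self.I_max < 0 or self.gain < 0 or self.noise_sigma < 0:
            raise InvalidParameterError("I_max, gain, noise_sigma must be >= 0")

    def response(self, C: np.ndarray) -> np.ndarray:
        """Expected (noise-free) intensity at concentration C (µM)."""
        C = np.asarray(C, dtype=float)
        if self.kind == "hypoxia_linear":
            sig = self.I_max * np.clip(1.0 - C / self.C_ref, 0.0, None)
        elif self.kind == "direct":
            sig = self.gain * C
        else:
            sig = self.I_max / (1.0 + np.exp((C - self.C_thr) / self.width))
        return self.background + sig


def sample_cells(
    density: DensityProfile,
    geom: ChamberGeometry | None = None,
    seed: int = 0,
    shell_width: float = 10.0,
) -> CellTable:
    """Draw cell positions from an inhomogeneous spatial Poisson process.

    The process is radially symmetric: the expected count in a thin shell is
    ρ(r)·2πr·dr, angles are uniform.  The domain is the density profile's
    radial support, clipped to the chamber (r ≤ r_outer).  Identical seeds
    give identical tables.
    """
    geom = geom or ChamberGeometry()
    rng = _rng(seed, _TAG_SAMPLE)
    r_lo = float(density.r[0])
    r_hi = min(float(density.r[-1]), geom.r_outer)
    edges = np.linspace(r_lo, r_hi, max(2, int(math.ceil((r_hi - r_lo) / shell_width)) + 1))
    mids = 0.5 * (edges[:-1] + edges[1:])
    areas = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    expected = density.at(mids) * areas
    counts = rng.poisson(expected)
    radii = []
    for lo, hi, c in zip(edges[:-1], edges[1:], counts):
        if c:
            u = rng.random(c)
            radii.append(np.sqrt(lo**2 + u * (hi**2 - lo**2)))
    r = np.concatenate(radii) if radii else np.empty(0)
    theta = rng.uniform(0.0, 2.0 * math.pi, r.size)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(r.size),
            "x_um": r * np.cos(theta),
            "y_um": r * np.sin(theta),
        }
    )
    return CellTable(df, center=(0.0, 0.0))


def assign_intensities(
    cells: CellTable,
    profile: ConcentrationProfile,
    model: IntensityModel,
    seed: int = 0,
    channel: str = "reporter",
    extend_inner: bool = True,
) -> CellTable:
    """Add a fluorescence channel responding to the local concentration.

    Each cell's intensity is ``response(C(r)) · exp(ε) + 0`` with
    ε ~ N(0, noise_sigma²) (the background enters inside ``response``).
    Cells at radii below the profile's inner radius sit under the aperture at
    the source concentration when ``extend_inner`` (the default); cells beyond
    the profile's outer radius are an error.
    """
    radii = cells.radii()
    r_prof = profile.r
    if radii.max() > r_prof[-1] + 1e-9:
        raise InvalidParameterError(
            f"cells extend to r={radii.max():.0f} µm beyond the concentration "
            f"profile (max {r_prof[-1]:.0f} µm)"
        )
    if not extend_inner and radii.min() < r_prof[0] - 1e-9:
        raise InvalidParameterError("cells inside the profile's inner radius")
    C = np.interp(radii, r_prof, profile.C)  # np.interp clamps at the ends
    expected = model.response(C)
    rng = _rng(seed, _TAG_ASSIGN)
    noise = (
        np.exp(rng.normal(0.0, model.noise_sigma, radii.size))
        if model.noise_sigma > 0
        else 1.0
    )
    data = cells.data.copy()
    data[channel] = expected * noise
    return CellTable(data, center=cells.center)


@dataclass(frozen=True)
class DiskSeriesParams:
    """Parameters of a phenomenological disk-formation time series.

    The cell density interpolates from an initially uniform monolayer to a
    disk with a logistic edge at ``final_radius`` — a descriptive stand-in
    for the death/migration/proliferation dynamics that concentrate cells
    around the aperture over days, not a mechanistic model of them.
    """

    initial_density: float = 2.0e-3  # cells/µm² (= 2e5 cells/cm²)
    final_radius: float = 1500.0
    edge_width: float = 100.0
    times_h: tuple[float, ...] = (0.0, 48.0, 96.0, 192.0)
    r_max: float = 6000.0

    def __post_init__(self) -> None:
        if self.final_radius <= 0 or self.final_radius > self.r_max:
            raise InvalidParameterError("need 0 < final_radius <= r_max")
        if self.initial_density < 0:
            raise InvalidParameterError("initial_density must be >= 0")
        if len(self.times_h) < 1 or any(
            b <= a for a, b in zip(self.times_h, self.times_h[1:])
        ):
            raise InvalidParameterError("times_h must be strictly increasing")


def make_disk_series(
    params: DiskSeriesParams,
    geom: ChamberGeometry | None = None,
    seed: int = 0,
) -> list[tuple[float, CellTable]]:
    """Time-stamped cell tables of a forming disk.

    At time fraction s = t/t_final the density is
    ρ(r) = ρ₀·[(1−s) + s·logistic((R−r)/w)], so the occupied radius shrinks
    monotonically from the full chamber to the target disk.
    """
    geom = geom or ChamberGeometry()
    if params.final_radius > geom.r_outer:
        raise InvalidParameterError("final_radius exceeds the chamber radius")
    t_final = params.times_h[-1]
    series = []
    r = np.linspace(0.0, min(params.r_max, geom.r_outer), 512)
    disk_shape = 1.0 / (1.0 + np.exp((r - params.final_radius) / params.edge_width))
    for i, t in enumerate(params.times_h):
        s = t / t_final if t_final > 0 else 1.0
        dens = params.initial_density * ((1.0 - s) + s * disk_shape)
        table = sample_cells(DensityProfile(r, dens), geom, seed=seed + i)
        series.append((t, table))
    return series


def render_image(
    cells: CellTable,
    channel: str,
    psf_sigma: float = 5.0,
    scale: float = 5.0,
    shape: tuple[int, int] = (512, 512),
    origin: tuple[float, float] = (0.0, 0.0),
    background: float = 0.0,
    tile_artifact: tuple[float, float] | None = None,
    shot_noise: bool = False,
    seed: int = 0,
    saturation_warn_fraction: float = 0.01,
) -> np.ndarray:
    """Render a 16-bit image of Gaussian spots at the cell positions.

    Each cell contributes a 2-D Gaussian of width ``psf_sigma`` (µm) whose
    *integral* equals the cell's intensity, so integrated image intensity is
    proportional to total cell intensity.  ``origin`` is the µm coordinate of
    pixel (0, 0); ``scale`` is µm/pixel.  ``tile_artifact=(amplitude,
    period_um)`` multiplies the image by a ±amplitude checkerboard with the
    given tile period, emulating stitching artifacts.  ``shot_noise`` applies
    Poisson noise.  All cells must lie inside the field; output is uint16
    with a warning if more than ``saturation_warn_fraction`` of pixels clip.
    """
    if channel not in cells.channels:
        raise InvalidParameterError(f"unknown channel {channel!r}")
    if psf_sigma <= 0 or scale <= 0:
        raise InvalidParameterError("psf_sigma and scale must be > 0")
    h, w = shape
    px = (cells.data["x_um"].to_numpy(float) - origin[0]) / scale
    py = (cells.data["y_um"].to_numpy(float) - origin[1]) / scale
    if len(cells) and (
        px.min() < 0 or py.min() < 0 or px.max() > w - 1 or py.max() > h - 1
    ):
        raise InvalidParameterError("cells fall outside the image field")
    img = np.full(shape, float(background))
    sig = psf_sigma / scale  # px
    half = max(1, int(math.ceil(4 * sig)))
    amp_norm = 1.0 / (2.0 * math.pi * sig**2)  # unit-integral Gaussian
    intens = cells.data[channel].to_numpy(float) if len(cells) else np.empty(0)
    for x0, y0, inten in zip(px, py, intens):
        j0, i0 = int(round(x0)), int(round(y0))
        jlo, jhi = max(0, j0 - half), min(w, j0 + half + 1)
        ilo, ihi = max(0, i0 - half), min(h, i0 + half + 1)
        jj = np.arange(jlo, jhi)
        ii = np.arange(ilo, ihi)
        gx = np.exp(-0.5 * ((jj - x0) / sig) ** 2)
        gy = np.exp(-0.5 * ((ii - y0) / sig) ** 2)
        img[ilo:ihi, jlo:jhi] += inten * amp_norm * np.outer(gy, gx)
    if tile_artifact is not None:
        amp, period = tile_artifact
        if amp < 0 or period <= 0:
            raise InvalidParameterError("tile amplitude >= 0 and period > 0 required")
        period_px = max(1, int(round(period / scale)))
        jj, ii = np.meshgrid(np.arange(w), np.arange(h))
        checker = ((jj // period_px) + (ii // period_px)) % 2
        img *= 1.0 + amp * (2.0 * checker - 1.0)
    if shot_noise:
        rng = _rng(seed, _TAG_RENDER)
        img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
    saturated = np.count_nonzero(img > 65535)
    if saturated > saturation_warn_fraction * img.size:
        warnings.warn(
            f"{saturated} pixels ({100 * saturated / img.size:.1f}%) saturate 16 bits",
            stacklevel=2,
        )
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)
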