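"""Radial quantification of per-cell fluorescence around a chamber aperture.

Segmented microscopy output arrives as a per-cell table (position in µm plus
one intensity column per fluorescence channel).  Cells are binned into annuli
of constant width (default 50 µm) around the aperture center and the mean
fluorescence intensity (MFI) per cell in each bin is computed with its SEM.
Downstream operations mirror the standard workflow for such data:
normalization (to the first point, the profile maximum, or an external
control), a truncated 5-point moving average against tile-stitching
oscillations, hypoxic-front detection (first distance at which the reporter
reaches a fraction — by convention 90% — of its maximum), fold changes of
fronts between conditions, disk-area change between time points, Pearson
correlation of two channels' profiles, and mean ± SEM aggregation across
replicate disks.

Conventions (stated because raw intensity tables do not carry them):

- bin edges are half-open ``[lo, hi)`` starting at 0 at the aperture center;
- empty bins propagate as gaps (NaN), never as zeros;
- SEM for a single-cell bin is undefined (NaN), distinct from 0;
- front detection takes the first crossing, linearly interpolated between
  bin centers; exact ties resolve to the smaller distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InvalidParameterError,
    NormalizationError,
    ProfileError,
    UndefinedCorrelationError,
    UndefinedFrontError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CellTable",
    "RadialProfile",
    "NormalizationState",
    "FrontEstimate",
    "DiskMask",
    "bin_cells",
    "pixel_radial_profile",
    "normalize_profile",
    "smooth_profile",
    "hypoxic_front",
    "front_fold_change",
    "disk_area_change",
    "correlate_channels",
    "aggregate_replicates",
]

_META_COLUMNS = ("cell_id", "x_um", "y_um")


@dataclass
class CellTable:
    """Per-cell positions (µm) and per-channel intensities.

    ``data`` must have columns ``cell_id, x_um, y_um`` plus one column per
    channel; ``center`` is the (x, y) position of the aperture center in µm.
    """

    data: pd.DataFrame
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        missing = [c for c in _META_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidParameterError(f"cell table missing columns: {missing}")
        if self.data["cell_id"].duplicated().any():
            raise InvalidParameterError("cell_id values must be unique")
        if not all(np.isfinite(self.center)):
            raise InvalidParameterError("center must be finite")
        for ch in self.channels:
            vals = self.data[ch].to_numpy(float)
            if np.any(vals < 0):
                raise InvalidParameterError(f"negative intensities in channel {ch!r}")

    @property
    def channels(self) -> list[str]:
        return [c for c in self.data.columns if c not in _META_COLUMNS]

    def __len__(self) -> int:
        return len(self.data)

    def radii(self) -> np.ndarray:
        """Distance of every cell from the aperture center, µm."""
        dx = self.data["x_um"].to_numpy(float) - self.center[0]
        dy = self.data["y_um"].to_numpy(float) - self.center[1]
        return np.hypot(dx, dy)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, center: tuple[float, float] = (0.0, 0.0)) -> "CellTable":
        return cls(pd.read_csv(path), center=center)


@dataclass(frozen=True)
class NormalizationState:
    """Which references a profile's distances/intensities are expressed in."""

    distance_mode: str = "absolute"
    intensity_mode: str = "raw"
    reference: float | None = None


@dataclass
class RadialProfile:
    """Binned radial intensity profile.

    ``bin_edges`` are contiguous half-open ``[lo, hi)`` edges of constant
    width; ``mfi`` is the per-bin mean intensity with NaN marking empty bins,
    ``sem`` the per-bin standard error (NaN where undefined, i.e. n < 2) and
    ``n`` the per-bin cell or pixel count.
    """

    bin_edges: np.ndarray
    mfi: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    normalization: NormalizationState = field(default_factory=NormalizationState)

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "mfi", np.asarray(self.mfi, dtype=float))
        object.__setattr__(self, "sem", np.asarray(self.sem, dtype=float))
        object.__setattr__(self, "n", np.asarray(self.n))
        widths = np.diff(edges)
        if edges.size < 2 or np.any(widths <= 0):
            raise ProfileError("bin edges must be increasing")
        if not np.allclose(widths, widths[0], rtol=1e-6):
            raise ProfileError("bin width must be constant")
        if self.mfi.size != edges.size - 1:
            raise ProfileError("mfi length must match number of bins")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-empty bins."""
        return ~np.isnan(self.mfi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_um": self.bin_edges[:-1],
                "bin_hi_um": self.bin_edges[1:],
                "mfi": self.mfi,
                "sem": self.sem,
                "n": self.n,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RadialProfile":
        df = pd.read_csv(path)
        edges = np.append(df["bin_lo_um"].to_numpy(), df["bin_hi_um"].iloc[-1])
        return cls(edges, df["mfi"].to_numpy(), df["sem"].to_numpy(), df["n"].to_numpy())


@dataclass(frozen=True)
class FrontEstimate:
    """Detected front: distance (µm or normalized), threshold context."""

    distance: float
    fraction: float
    max_value: float
    crossing_bin: int


@dataclass
class DiskMask:
    """Binary disk mask with a physical scale, or a measured disk radius."""

    mask: np.ndarray | None = None
    scale: float = 1.0
    radius_um: float | None = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise InvalidParameterError("scale must be > 0")
        if self.mask is None and self.radius_um is None:
            raise InvalidParameterError("provide a mask or a radius")

    @property
    def area_um2(self) -> float:
        if self.mask is not None:
            return float(np.count_nonzero(self.mask)) * self.scale**2
        return math.pi * self.radius_um**2


def _bin_means(radii, values, bin_width, max_radius):
    """Shared binning core: returns (edges, mean, sem, n)."""
    if max_radius is not None:
        keep = radii < max_radius
        dropped = int((~keep).sum())
        if dropped:
            logger.info("excluding %d points beyond %.0f µm", dropped, max_radius)
        radii, values = radii[keep], values[keep]
    if radii.size == 0:
        raise ProfileError("no points fall inside the binning range")
    n_bins = int(np.floor(radii.max() / bin_width)) + 1
    edges = bin_width * np.arange(n_bins + 1, dtype=float)
    idx = np.minimum((radii // bin_width).astype(int), n_bins - 1)
    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    counts = np.bincount(idx, minlength=n_bins)
    for b in np.nonzero(counts)[0]:
        v = values[idx == b]
        mean[b] = v.mean()
        if v.size > 1:
            sem[b] = v.std(ddof=1) / math.sqrt(v.size)
    return edges, mean, sem, counts


def bin_cells(
    cells: CellTable,
    channel: str,
    bin_width: float = 50.0,
    max_radius: float | None = None,
) -> RadialProfile:
    """Bin cells into annuli and compute the mean intensity (MFI) per bin.

    Bins are ``[0, w), [w, 2w), ...`` from the aperture center; SEM is
    sd/√n per bin (NaN for single-cell bins); empty bins are NaN gaps.
    Cells at or beyond ``max_radius`` (e.g. outside the chamber) are excluded
    with a logged count rather than an error.
    """
    if len(cells) == 0:
        raise ProfileError("cell table is empty")
    if channel not in cells.channels:
        raise InvalidParameterError(
            f"unknown channel {channel!r}; available: {cells.channels}"
        )
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be > 0")
    edges, mean, sem, counts = _bin_means(
        cells.radii(), cells.data[channel].to_numpy(float), bin_width, max_radius
    )
    return RadialProfile(edges, mean, sem, counts)


def pixel_radial_profile(
    image: np.ndarray,
    center: tuple[float, float],
    bin_width: float = 50.0,
    scale: float = 1.0,
    max_radius: float | None = None,
) -> RadialProfile:
    """Radial profile of a raster image: mean pixel value per radial bin.

    ``center`` is (x, y) in µm in pixel-index coordinates scaled by
    ``scale`` (µm/pixel); it must lie inside the image.  Equivalent to the
    classic radial-profile average of all pixels at each radius, binned at
    ``bin_width``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidParameterError("image must be 2-D")
    cx, cy = center
    h, w = image.shape
    if not (0 <= cx <= (w - 1) * scale and 0 <= cy <= (h - 1) * scale):
        raise InvalidParameterError("center lies outside the image")
    yy, xx = np.mgrid[0:h, 0:w]
    radii = np.hypot(xx * scale - cx, yy * scale - cy).ravel()
    edges, mean, sem, counts = _bin_means(radii, image.ravel(), bin_width, max_radius)
    return RadialProfile(edges, mean, sem, counts)


_INTENSITY_MODES = ("first_point", "max", "external_reference")
_DISTANCE_MODES = ("absolute", "relative_to_disk_radius", "relative_depth")


def normalize_profile(
    profile: RadialProfile,
    intensity_mode: str = "first_point",
    distance_mode: str = "absolute",
    reference: float | None = None,
    disk_radius: float | None = None,
    max_depth: float | None = None,
) -> RadialProfile:
    """Express a profile relative to a reference intensity and/or distance.

    ``first_point`` divides by the first non-empty bin's MFI (the value at the
    aperture), ``max`` by the profile maximum, ``external_reference`` by a
    supplied control value (e.g. the control group's first point).  Distances
    can be divided by a disk radius or a maximum depth so replicate disks of
    different sizes share a 0-1 axis.
    """
    if intensity_mode not in _INTENSITY_MODES:
        raise InvalidParameterError(f"intensity_mode must be one of {_INTENSITY_MODES}")
    if distance_mode not in _DISTANCE_MODES:
        raise InvalidParameterError(f"distance_mode must be one of {_DISTANCE_MODES}")

    valid = profile.valid
    if not valid.any():
        raise ProfileError("profile has no non-empty bins")
    if intensity_mode == "first_point":
        ref = float(profile.mfi[np.argmax(valid)])
    elif intensity_mode == "max":
        ref = float(np.nanmax(profile.mfi))
    else:
        if reference is None:
            raise NormalizationError("external_reference mode needs a reference value")
        ref = float(reference)
    if ref == 0:
        raise NormalizationError("normalization reference is zero")

    edges = profile.bin_edges
    if distance_mode == "relative_to_disk_radius":
        if not disk_radius or disk_radius <= 0:
            raise NormalizationError("relative_to_disk_radius needs disk_radius > 0")
        edges = edges / disk_radius
    elif distance_mode == "relative_depth":
        if not max_depth or max_depth <= 0:
            raise NormalizationError("relative_depth needs max_depth > 0")
        edges = edges / max_depth

    return RadialProfile(
        edges,
        profile.mfi / ref,
        profile.sem / ref,
        profile.n.copy(),
        NormalizationState(distance_mode, intensity_mode, ref),
    )


def smooth_profile(profile: RadialProfile, window: int = 5) -> RadialProfile:
    """Centered moving average; the window truncates at the profile edges.

    NaN gaps are skipped inside each window (a bin surrounded entirely by
    gaps stays NaN).  ``window`` must be odd; ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise InvalidParameterError("window must be odd and >= 1")
    half = window // 2
    v = profile.mfi
    out = np.full_like(v, np.nan)
    for i in range(v.size):
        chunk = v[max(0, i - half): i + half + 1]
        if np.any(~np.isnan(chunk)):
            out[i] = np.nanmean(chunk)
    return RadialProfile(
        profile.bin_edges.copy(), out, profile.sem.copy(), profile.n.copy(),
        profile.normalization,
    )


def hypoxic_front(profile: RadialProfile, fraction: float = 0.9) -> FrontEstimate:
    """First distance at which the profile reaches ``fraction`` of its maximum.

    Scans outward from the center over non-empty bins; the crossing is
    linearly interpolated between adjacent bin centers.  A profile already at
    or above the threshold in its first bin fronts at that bin's center.
    """
    if not (0 < fraction <= 1):
        raise InvalidParameterError("fraction must be in (0, 1]")
    valid = profile.valid
    if valid.sum() < 2:
        raise ProfileError("need at least 2 non-empty bins")
    centers = profile.bin_centers[valid]
    values = profile.mfi[valid]
    vmax = float(values.max())
    if np.all(values == values[0]):
        raise UndefinedFrontError("profile is flat; front undefined")
    threshold = fraction * vmax
    at_or_above = values >= threshold
    i = int(np.argmax(at_or_above))
    if i == 0:
        distance = float(centers[0])
    else:
        v0, v1 = values[i - 1], values[i]
        frac = (threshold - v0) / (v1 - v0) if v1 != v0 else 0.0
        distance = float(centers[i - 1] + frac * (centers[i] - centers[i - 1]))
    return FrontEstimate(distance, fraction, vmax, int(np.nonzero(valid)[0][i]))


def front_fold_change(
    front_treated: FrontEstimate | float, front_control: FrontEstimate | float
) -> float:
    """Treated front distance / control front distance."""
    t = front_treated.distance if isinstance(front_treated, FrontEstimate) else front_treated
    c = front_control.distance if isinstance(front_control, FrontEstimate) else front_control
    if c == 0:
        raise InvalidParameterError("control front distance is zero")
    return float(t) / float(c)


def disk_area_change(mask_t0: DiskMask, mask_t1: DiskMask) -> float:
    """Percent change in disk area between two time points: 100·(A₁−A₀)/A₀."""
    if mask_t0.mask is not None and mask_t1.mask is not None:
        if mask_t0.scale != mask_t1.scale:
            raise InvalidParameterError("masks must share the same scale")
    a0 = mask_t0.area_um2
    a1 = mask_t1.area_um2
    if a0 == 0:
        raise ProfileError("t0 mask is empty")
    return 100.0 * (a1 - a0) / a0


def correlate_channels(profile_a: RadialProfile, profile_b: RadialProfile) -> float:
    """Pearson correlation of two profiles over their paired non-empty bins."""
    if profile_a.bin_edges.size != profile_b.bin_edges.size or not np.allclose(
        profile_a.bin_edges, profile_b.bin_edges
    ):
        raise ProfileError("profiles must share the same bin structure")
    paired = profile_a.valid & profile_b.valid
    if paired.sum() < 3:
        raise UndefinedCorrelationError("need >= 3 paired non-empty bins")
    a = profile_a.mfi[paired]
    b = profile_b.mfi[paired]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero variance in one of the profiles")
    return float(stats.pearsonr(a, b).statistic)


def aggregate_replicates(profiles: list[RadialProfile]) -> RadialProfile:
    """Mean ± SEM across replicate profiles, per bin.

    All replicates must share the same normalization state.  Replicates on
    different grids are allowed only after relative-distance normalization, in
    which case they are linearly interpolated onto the first replicate's bin
    centers.  Gaps are skipped per bin (not imputed); ``n`` reports the
    replicate count contributing to each bin, and SEM is NaN where fewer than
    two replicates contribute.
    """
    if not profiles:
        raise ProfileError("no profiles to aggregate")
    state = profiles[0].normalization
    for p in profiles[1:]:
        if p.normalization != state:
            raise ProfileError("mixed normalization states")
    base = profiles[0]
    same_grid = all(
        p.bin_edges.size == base.bin_edges.size
        and np.allclose(p.bin_edges, base.bin_edges)
        for p in profiles
    )
    if not same_grid:
        if state.distance_mode == "absolute":
            raise ProfileError(
                "replicates on different grids need relative-distance normalization"
            )
        centers = base.bin_centers
        rows = []
        for p in profiles:
            v = p.valid
            rows.append(
                np.interp(centers, p.bin_centers[v], p.mfi[v], left=np.nan, right=np.nan)
            )
        stack = np.vstack(rows)
    else:
        stack = np.vstack([p.mfi for p in profiles])

    counts = np.sum(~np.isnan(stack), axis=0)
    mean = np.full(counts.size, np.nan)
    sem = np.full(counts.size, np.nan)
    has = counts > 0
    mean[has] = np.nanmean(stack[:, has], axis=0)
    two = counts > 1
    sem[two] = np.nanstd(stack[:, two], axis=0, ddof=1) / np.sqrt(counts[two])
    return RadialProfile(base.bin_edges.copy(), mean, sem, counts, state)
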