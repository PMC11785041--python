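"""Power spectral density of fluorescence images and its radial reduction.

For incoherent fluorescence the "exit wave" psi(x, y) is the square root of
the per-element intensity image (spectrum-fitting residuals can leave small
negative pixels; the whole image is first offset by the magnitude of the most
negative pixel, which only changes the zero-frequency term).  The 2D power
spectral density is

    S(ux, uy) = |DFT(psi)|^2

with the unnormalized forward transform, cyclically shifted so that the zero
spatial frequency sits at the central pixel of an even-size grid.  Frequency
axes are physical, in inverse micrometers: for an even length N and pixel
step d, the axis runs from -1/(2d) up to (N/2 - 1)/(N d).

The 2D spectrum is reduced to a 1D profile S(ur), ur = sqrt(ux^2 + uy^2), by
averaging over annular bins — optionally restricted to azimuthal sectors
about the x or y frequency axis to resolve directional resolution
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maps_io import ElementalMap

_SECTOR_MODES = ("isotropic", "x_sector", "y_sector")

#: Minimum grid side for a meaningful spectral analysis.
MIN_ANALYSIS_SIZE = 4


@dataclass
class ExitWave:
    """Square-root amplitude image used for spectral analysis.

    ``offset`` is the constant added to the intensity image before taking the
    square root: zero for a non-negative map, otherwise the magnitude of the
    most negative pixel.
    """

    psi: np.ndarray
    offset: float
    dx: float
    dy: float

    @property
    def ny(self) -> int:
        return self.psi.shape[0]

    @property
    def nx(self) -> int:
        return self.psi.shape[1]


@dataclass
class Spectrum2D:
    """Zero-centered 2D power spectral density with physical frequency axes.

    ``S[iy, ix]`` corresponds to frequencies ``(uy_axis[iy], ux_axis[ix])``
    in inverse micrometers; the zero frequency is at index ``(ny//2, nx//2)``.
    """

    S: np.ndarray
    ux_axis: np.ndarray
    uy_axis: np.ndarray
    dx: float
    dy: float

    @property
    def ny(self) -> int:
        return self.S.shape[0]

    @property
    def nx(self) -> int:
        return self.S.shape[1]

    def frequency_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Return broadcast ``(UX, UY)`` grids matching the shape of ``S``."""
        return np.meshgrid(self.ux_axis, self.uy_axis)


@dataclass(frozen=True)
class SectorSpec:
    """Azimuthal selection for the radial average.

    ``isotropic`` keeps every pixel.  ``x_sector`` keeps pixels whose acute
    angle from the x frequency axis is strictly below ``half_angle`` degrees
    (both point-symmetric half-planes); ``y_sector`` keeps the complementary
    wedge about the y axis, including its boundary, so that the two 45-degree
    sectors partition the off-axis plane exactly.
    """

    mode: str = "isotropic"
    half_angle: float = 30.0

    def __post_init__(self) -> None:
        if self.mode not in _SECTOR_MODES:
            raise ValueError(f"sector mode must be one of {_SECTOR_MODES}")
        if self.mode != "isotropic" and not (0.0 < self.half_angle <= 45.0):
            raise ValueError("half_angle must be in (0, 45] degrees")


@dataclass
class RadialProfile:
    """Radially binned PSD: mean S per annulus of ur, with occupancy counts.

    Bins are uniform in ur from 0 to the maximum frequency present in the
    kept (sector-filtered) pixel set; empty bins carry ``counts == 0`` and a
    NaN mean, and are excluded from any downstream fit.
    """

    ur_centers: np.ndarray
    S_values: np.ndarray
    counts: np.ndarray
    sector: SectorSpec = field(default_factory=SectorSpec)

    @property
    def n_bins(self) -> int:
        return len(self.ur_centers)

    @property
    def ur_max(self) -> float:
        """Largest bin center with any occupancy."""
        occupied = self.counts > 0
        return float(self.ur_centers[occupied][-1])

    def occupied(self) -> "RadialProfile":
        """Return a view restricted to non-empty bins."""
        keep = self.counts > 0
        return RadialProfile(self.ur_centers[keep], self.S_values[keep],
                             self.counts[keep], self.sector)


def to_exit_wave(emap: ElementalMap) -> ExitWave:
    """Square-root amplitude of a map, offsetting negatives first.

    The offset equals the magnitude of the most negative pixel (zero when
    none), so the shifted image has minimum exactly 0 when a negative pixel
    existed.
    """
    if min(emap.values.shape) < MIN_ANALYSIS_SIZE:
        raise ValueError(
            f"map shape {emap.values.shape} too small for spectral analysis "
            f"(need at least {MIN_ANALYSIS_SIZE} pixels per axis)"
        )
    lowest = float(emap.values.min())
    offset = -lowest if lowest < 0 else 0.0
    shifted = emap.values + offset
    # guard against -0.0 / rounding residue at the shifted minimum
    np.maximum(shifted, 0.0, out=shifted)
    return ExitWave(np.sqrt(shifted), offset=offset, dx=emap.dx, dy=emap.dy)


def pad_to_even(wave: ExitWave) -> ExitWave:
    """Extend odd dimensions by one row/column filled with the mean of psi.

    The mean is that of the unpadded exit wave; even dimensions are returned
    unchanged (same object).
    """
    ny, nx = wave.psi.shape
    if ny % 2 == 0 and nx % 2 == 0:
        return wave
    fill = float(wave.psi.mean())
    pad_y = ny % 2
    pad_x = nx % 2
    psi = np.pad(wave.psi, ((0, pad_y), (0, pad_x)), constant_values=fill)
    return ExitWave(psi, offset=wave.offset, dx=wave.dx, dy=wave.dy)


def compute_psd(wave: ExitWave) -> Spectrum2D:
    """Unnormalized-DFT power spectrum, zero frequency at the central pixel.

    Requires even dimensions (apply :func:`pad_to_even` first); the even size
    is what puts ur = 0 exactly on a pixel after the cyclic shift.
    """
    ny, nx = wave.psi.shape
    if ny % 2 or nx % 2:
        raise ValueError(f"PSD requires even dimensions, got {wave.psi.shape}")
    F = np.fft.fftshift(np.fft.fft2(wave.psi))
    S = (F * F.conj()).real
    ux_axis = np.fft.fftshift(np.fft.fftfreq(nx, d=wave.dx))
    uy_axis = np.fft.fftshift(np.fft.fftfreq(ny, d=wave.dy))
    return Spectrum2D(S, ux_axis=ux_axis, uy_axis=uy_axis, dx=wave.dx, dy=wave.dy)


def sector_mask(spec: Spectrum2D, sector: SectorSpec) -> np.ndarray:
    """Boolean mask of pixels kept by the sector, excluding ur = 0.

    The angle test uses the acute angle between (ux, uy) and the sector axis;
    point symmetry is implicit (absolute frequency components).  x sectors
    use a strict ``angle < half_angle`` test and y sectors the complementary
    ``(90 - angle) <= half_angle`` test, so boundaries are half-open and the
    two 45-degree sectors tile the plane without overlap or gap.
    """
    UX, UY = spec.frequency_grids()
    ur = np.hypot(UX, UY)
    mask = ur > 0
    if sector.mode == "isotropic":
        return mask
    angle_from_x = np.degrees(np.arctan2(np.abs(UY), np.abs(UX)))
    if sector.mode == "x_sector":
        return mask & (angle_from_x < sector.half_angle)
    return mask & (angle_from_x >= 90.0 - sector.half_angle)


def radial_profile(
    spec: Spectrum2D,
    n_bins: int | None = None,
    sector: SectorSpec | None = None,
) -> RadialProfile:
    """Average the 2D PSD into annular bins of ur = sqrt(ux^2 + uy^2).

    Parameters
    ----------
    spec : Spectrum2D
    n_bins : int, optional
        Number of uniform ur bins between 0 and the largest frequency present
        in the kept pixel set (corner frequencies included).  Defaults to
        ``min(nx, ny) // 2``, one bin per resolvable step of the smaller axis.
    sector : SectorSpec, optional
        Azimuthal restriction; defaults to isotropic.

    The central ur = 0 pixel is always excluded.  Each kept pixel falls in
    bin ``floor(ur / ur_top * n_bins)`` (half-open bins, the top edge closed),
    and the bin value is the arithmetic mean of S over its pixels.
    """
    sector = sector or SectorSpec()
    if n_bins is None:
        n_bins = min(spec.nx, spec.ny) // 2
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mask = sector_mask(spec, sector)
    if not mask.any():
        raise ValueError(f"sector {sector} selects no pixels")
    UX, UY = spec.frequency_grids()
    ur = np.hypot(UX, UY)[mask]
    s = spec.S[mask]
    ur_top = ur.max()
    idx = np.minimum((ur / ur_top * n_bins).astype(np.intp), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=s, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = np.linspace(0.0, ur_top, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(centers, means, counts, sector)


def map_psd_profile(
    emap: ElementalMap,
    n_bins: int | None = None,
    sector: SectorSpec | None = None,
) -> RadialProfile:
    """Convenience pipeline: map -> exit wave -> pad -> PSD -> radial profile."""
    return radial_profile(compute_psd(pad_to_even(to_exit_wave(emap))),
                          n_bins=n_bins, sector=sector)
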