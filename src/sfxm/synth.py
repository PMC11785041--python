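"""Synthetic elemental maps with known ground truth.

Real fluorescence maps of tissue have two robust spectral features: an
isotropic power-law fall-off ``S(ur) ~ ur**a`` of the underlying structure,
and a flat high-frequency noise floor from per-pixel Poisson counting
statistics.  The generators here produce integer-count maps with exactly
those ingredients and a known ground truth, so every analysis stage can be
validated without experimental data:

* ``power_law_field`` — a random field with prescribed isotropic spectral
  slope, rescaled to a target mean count rate and Poisson-sampled;
* ``flat_field`` — a constant rate, isolating the noise floor;
* ``spot_pair`` — two Gaussian spots on a weak background, a real-space
  sanity check that the spectral resolution estimate tracks separability.

Randomness is split into independent streams for the field phases and the
Poisson draws, so changing the count level does not change the underlying
structure — mirroring what longer dwell times do at a real instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .maps_io import ElementalMap

_KINDS = ("power_law_field", "flat_field", "spot_pair")

# substream tags for the per-purpose RNG split
_STREAM_FIELD = 1
_STREAM_POISSON = 2


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters of a generated map.

    Defaults describe a map this instrument class would plausibly produce:
    256 x 256 pixels of 1 um, spectral exponent -3.5 (natural images and
    tissue maps mostly fall between -3 and -4), fractional structure contrast
    0.5 (RMS of the modulation about the mean), and a mean of 200 detected
    counts per pixel.
    """

    nx: int = 256
    ny: int = 256
    dx: float = 1.0
    dy: float = 1.0
    a_true: float = -3.5
    amplitude: float = 0.5
    mean_counts: float = 200.0
    seed: int = 0
    kind: str = "power_law_field"
    spot_separation: float | None = None
    element: str = "synthetic"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.nx % 2 or self.ny % 2 or self.nx < 16 or self.ny < 16:
            raise ValueError(
                f"nx, ny must be even and >= 16, got ({self.nx}, {self.ny})"
            )
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("pixel steps must be positive")
        if self.mean_counts <= 0:
            raise ValueError(f"mean_counts must be positive, got {self.mean_counts}")
        if self.kind == "power_law_field" and self.a_true >= 0:
            raise ValueError(f"a_true must be negative, got {self.a_true}")
        if self.kind == "power_law_field" and self.amplitude <= 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if self.kind == "spot_pair":
            if self.spot_separation is None or self.spot_separation <= 0:
                raise ValueError("spot_pair requires spot_separation > 0")
            if (self.spot_separation > self.nx * self.dx
                    or self.spot_separation > self.ny * self.dy):
                raise ValueError(
                    f"spot_separation {self.spot_separation} um exceeds the "
                    f"field ({self.nx * self.dx} x {self.ny * self.dy} um)"
                )


@dataclass
class SyntheticResult:
    """Generated integer-count map together with its noiseless truth."""

    map: ElementalMap
    truth: np.ndarray
    spec: SyntheticSpec


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _poisson_map(spec: SyntheticSpec, truth: np.ndarray) -> SyntheticResult:
    counts = _rng(spec, _STREAM_POISSON).poisson(truth).astype(np.float64)
    emap = ElementalMap(counts, spec.dx, spec.dy, element=spec.element,
                        source="synthetic")
    return SyntheticResult(emap, truth, spec)


def _power_law_field(spec: SyntheticSpec) -> np.ndarray:
    """Zero-mean, unit-variance real field with isotropic PSD ~ ur**a_true.

    White Gaussian noise is shaped in Fourier space by ur**(a_true/2); the
    zero-frequency amplitude (singular under the power law) is set to zero
    here and restored from the requested mean below.
    """
    g = _rng(spec, _STREAM_FIELD).standard_normal((spec.ny, spec.nx))
    G = np.fft.fft2(g)
    ux = np.fft.fftfreq(spec.nx, d=spec.dx)
    uy = np.fft.fftfreq(spec.ny, d=spec.dy)
    ur = np.hypot(*np.meshgrid(ux, uy))
    shaping = np.zeros_like(ur)
    nz = ur > 0
    shaping[nz] = ur[nz] ** (spec.a_true / 2.0)
    f = np.fft.ifft2(G * shaping).real
    f -= f.mean()
    f /= f.std()
    return f


def generate_power_law_map(spec: SyntheticSpec) -> SyntheticResult:
    """Poisson-sampled map whose structure has spectral slope ``a_true``.

    The rate field is ``1 + amplitude * f`` with f the unit-variance shaped
    field, shifted by its minimum if negative (a DC-only change) and rescaled
    to mean ``mean_counts``; hard clipping is avoided so the slope of the
    spectrum is not distorted.
    """
    if spec.kind != "power_law_field":
        raise ValueError(f"spec.kind is {spec.kind!r}, expected 'power_law_field'")
    field = 1.0 + spec.amplitude * _power_law_field(spec)
    lowest = field.min()
    if lowest < 0:
        field = field - lowest
    truth = field * (spec.mean_counts / field.mean())
    return _poisson_map(spec, truth)


def generate_flat_field(spec: SyntheticSpec) -> SyntheticResult:
    """Constant rate ``mean_counts`` with i.i.d. Poisson counts per pixel."""
    if spec.kind != "flat_field":
        raise ValueError(f"spec.kind is {spec.kind!r}, expected 'flat_field'")
    truth = np.full((spec.ny, spec.nx), float(spec.mean_counts))
    return _poisson_map(spec, truth)


def generate_spot_pair(spec: SyntheticSpec) -> SyntheticResult:
    """Two equal-integral Gaussian spots on a low uniform background.

    Spots of FWHM ``spot_separation / 2`` are centered symmetrically about
    the field center along x, separated by ``spot_separation`` um.  The
    background is 10% of the overall mean; the rate field is rescaled so its
    mean is ``mean_counts``.
    """
    if spec.kind != "spot_pair":
        raise ValueError(f"spec.kind is {spec.kind!r}, expected 'spot_pair'")
    sep = float(spec.spot_separation)  # validated > 0
    fwhm = sep / 2.0
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    x = (np.arange(spec.nx) - (spec.nx - 1) / 2.0) * spec.dx
    y = (np.arange(spec.ny) - (spec.ny - 1) / 2.0) * spec.dy
    X, Y = np.meshgrid(x, y)
    spots = np.zeros_like(X)
    for cx in (-sep / 2.0, sep / 2.0):
        spots += np.exp(-((X - cx) ** 2 + Y**2) / (2.0 * sigma**2))
    background = 0.1 * spots.mean() / 0.9  # background carries 10% of the mean
    truth = spots + background
    truth *= spec.mean_counts / truth.mean()
    return _poisson_map(spec, truth)


def generate(spec: SyntheticSpec) -> SyntheticResult:
    """Dispatch on ``spec.kind``."""
    return {
        "power_law_field": generate_power_law_map,
        "flat_field": generate_flat_field,
        "spot_pair": generate_spot_pair,
    }[spec.kind](spec)


def rescaled_counts(spec: SyntheticSpec, mean_counts: float) -> SyntheticResult:
    """Same ground-truth structure at a different count level.

    Because field phases and Poisson draws use separate seed streams, only
    the photon statistics change — the synthetic analogue of re-scanning the
    same sample with a different dwell time.
    """
    return generate(replace(spec, mean_counts=mean_counts))
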