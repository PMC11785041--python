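"""Power-law/noise-floor fitting of radial PSD profiles and derived resolution.

Photon-limited fluorescence images show a radial power spectrum that falls
off as a power law in spatial frequency,

    S(ur) ~= P * ur**a,   a < 0,

until uncorrelated Poisson counting noise flattens it into a constant floor
S_nf (white in frequency because pixel noise is delta-correlated in space).
A line fit of log S against log ur below the "knee" gives P and a; the floor
is the average of bins above the knee.  The knee frequency solves
P * u**a = S_nf:

    u_knee = (S_nf / P) ** (1 / a),

and the resolution-defining frequency applies the Rose criterion, requiring
the signal to exceed the floor by a factor SNR_res (5 by default):

    u_res = (SNR_res * S_nf / P) ** (1 / a),    delta_res = 1 / (2 * u_res).

The same (P, a, S_nf) triple defines the Wiener filter
W(ur) = P ur^a / (P ur^a + S_nf) used for noise suppression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .maps_io import ElementalMap
from .psd import RadialProfile, SectorSpec, to_exit_wave


@dataclass(frozen=True)
class FitRanges:
    """Inclusive frequency bounds (1/um) of the signal-fit and noise-floor bins.

    The signal range must lie strictly below the noise range:
    ``signal_lo < signal_hi <= noise_lo < noise_hi``.
    """

    signal_lo: float
    signal_hi: float
    noise_lo: float
    noise_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.signal_lo < self.signal_hi <= self.noise_lo < self.noise_hi):
            raise ValueError(
                "fit ranges must satisfy signal_lo < signal_hi <= noise_lo < noise_hi; "
                f"got {self}"
            )


@dataclass
class PowerLawFit:
    """Fitted signal law, noise floor and derived resolution quantities.

    ``valid`` is False when the fitted exponent is non-negative (no decaying
    signal trend), in which case the derived frequencies are NaN.
    ``out_of_band`` flags a u_res beyond the largest frequency of the fitted
    profile: the image is then optic- rather than noise-limited and the
    extrapolated resolution should be read as a bound.
    """

    P: float
    a: float
    S_nf: float
    snr_res: float
    u_knee: float
    u_res: float
    delta_res: float
    ranges: FitRanges
    sector: SectorSpec = field(default_factory=SectorSpec)
    element: str = ""
    valid: bool = True
    out_of_band: bool = False

    def to_dict(self) -> dict[str, Any]:
        return {
            "element": self.element,
            "sector_mode": self.sector.mode,
            "sector_half_angle_deg": self.sector.half_angle,
            "P": self.P,
            "a": self.a,
            "S_nf": self.S_nf,
            "snr_res": self.snr_res,
            "u_knee_per_um": self.u_knee,
            "u_res_per_um": self.u_res,
            "delta_res_um": self.delta_res,
            "signal_range_per_um": [self.ranges.signal_lo, self.ranges.signal_hi],
            "noise_range_per_um": [self.ranges.noise_lo, self.ranges.noise_hi],
            "valid": self.valid,
            "out_of_band": self.out_of_band,
        }


def _range_bins(profile: RadialProfile, lo: float, hi: float) -> np.ndarray:
    """Indices of occupied bins whose centers fall in [lo, hi]."""
    ur = profile.ur_centers
    return np.flatnonzero((profile.counts > 0) & (ur >= lo) & (ur <= hi))


def fit_signal(profile: RadialProfile, ranges: FitRanges) -> tuple[float, float]:
    """Unweighted least-squares line through (log ur, log S) over the signal range.

    Returns ``(P, a)`` with ``P = exp(intercept)`` and ``a = slope``.
    """
    idx = _range_bins(profile, ranges.signal_lo, ranges.signal_hi)
    if len(idx) < 2:
        raise ValueError(
            f"signal range [{ranges.signal_lo}, {ranges.signal_hi}] holds "
            f"{len(idx)} usable bins; need at least 2"
        )
    ur = profile.ur_centers[idx]
    s = profile.S_values[idx]
    if np.any(s <= 0) or np.any(ur <= 0):
        raise ValueError("signal-range bins must have positive ur and S for a log fit")
    a, log_p = np.polyfit(np.log(ur), np.log(s), 1)
    return float(np.exp(log_p)), float(a)


def estimate_noise_floor(profile: RadialProfile, ranges: FitRanges) -> float:
    """Arithmetic mean of S over the occupied bins in the noise range."""
    idx = _range_bins(profile, ranges.noise_lo, ranges.noise_hi)
    if len(idx) == 0:
        raise ValueError(
            f"noise range [{ranges.noise_lo}, {ranges.noise_hi}] holds no usable bins"
        )
    return float(profile.S_values[idx].mean())


def knee_frequency(P: float, a: float, S_nf: float) -> float:
    """Frequency where the fitted power law crosses the noise floor."""
    if P <= 0 or S_nf <= 0:
        raise ValueError(f"P and S_nf must be positive (P={P}, S_nf={S_nf})")
    if a >= 0:
        raise ValueError(f"power-law exponent must be negative, got a={a}")
    return float((S_nf / P) ** (1.0 / a))


def resolution(P: float, a: float, S_nf: float,
               snr_res: float = 5.0) -> tuple[float, float]:
    """Rose-criterion resolution frequency and half-period resolution.

    ``u_res = (snr_res * S_nf / P)**(1/a)`` and ``delta_res = 1/(2 u_res)``;
    ``snr_res = 1`` reduces u_res to the knee frequency.
    """
    if snr_res < 1:
        raise ValueError(f"snr_res must be >= 1, got {snr_res}")
    u_res = knee_frequency(P, a, snr_res * S_nf)
    return u_res, 1.0 / (2.0 * u_res)


def wiener_weights(P: float, a: float, S_nf: float, ur: np.ndarray) -> np.ndarray:
    """Wiener filter W(ur) = P ur^a / (P ur^a + S_nf) on a frequency grid.

    Values lie in [0, 1] and are non-increasing in ur for a < 0.  The ur = 0
    entry (power law singular there) is assigned weight 1: the mean level is
    passed through untouched.
    """
    if P <= 0:
        raise ValueError(f"P must be positive, got {P}")
    if a >= 0:
        raise ValueError(f"power-law exponent must be negative, got a={a}")
    if S_nf < 0:
        raise ValueError(f"noise floor must be non-negative, got {S_nf}")
    ur = np.asarray(ur, dtype=np.float64)
    w = np.ones_like(ur)
    nz = ur > 0
    if S_nf > 0:
        # divide by (1 + S_nf/(P ur^a)) for stability at tiny ur
        w[nz] = 1.0 / (1.0 + (S_nf / P) * ur[nz] ** (-a))
    return w


def apply_wiener(emap: ElementalMap, fit: PowerLawFit) -> ElementalMap:
    """Wiener-filter a map in the Fourier domain of its exit wave.

    The exit wave (square root of the offset image) is transformed, each
    Fourier coefficient is multiplied by W(ur) with the zero-frequency
    coefficient kept at weight 1, the result is inverse-transformed, squared,
    and the offset subtracted.  Small negatives from the offset subtraction
    are preserved, keeping the operation linear-algebraically honest.  Output
    shape equals input shape (no padding is needed: the filter is applied on
    the native DFT grid).
    """
    if not fit.valid or fit.a >= 0:
        raise ValueError("cannot Wiener-filter with an invalid fit (a >= 0)")
    wave = to_exit_wave(emap)
    F = np.fft.fft2(wave.psi)
    ux = np.fft.fftfreq(emap.nx, d=emap.dx)
    uy = np.fft.fftfreq(emap.ny, d=emap.dy)
    ur = np.hypot(*np.meshgrid(ux, uy))
    W = wiener_weights(fit.P, fit.a, fit.S_nf, ur)
    psi_f = np.fft.ifft2(F * W)
    residue = np.abs(psi_f.imag).max() / max(np.abs(psi_f.real).max(), 1e-300)
    if residue > 1e-9:
        warnings.warn(f"imaginary residue {residue:.2e} after symmetric filtering")
    filtered = psi_f.real ** 2 - wave.offset
    return ElementalMap(filtered, emap.dx, emap.dy, emap.element,
                        emap.dwell_ms, emap.source)


def suggest_ranges(profile: RadialProfile, noise_fraction: float = 0.2,
                   snr_cut: float = 10.0) -> FitRanges:
    """Heuristic fit ranges from the shape of a profile.  Always overridable.

    The noise range is the top ``noise_fraction`` of occupied frequencies;
    the signal range is the decade ending at the highest frequency whose
    binned PSD still exceeds ``snr_cut`` times the provisional floor, which
    keeps the log-log fit safely below the knee where the floor would bias
    the slope.  Explicit ranges chosen by inspecting the profile are always
    preferable for publication-grade numbers.
    """
    occ = profile.occupied()
    if occ.n_bins < 8:
        raise ValueError("profile too short for heuristic range selection")
    ur = occ.ur_centers
    s = occ.S_values
    n_noise = max(1, int(round(noise_fraction * len(ur))))
    noise_lo = float(ur[len(ur) - n_noise])
    noise_hi = float(ur[-1])
    floor = float(s[len(ur) - n_noise:].mean())
    above = np.flatnonzero(s > snr_cut * floor)
    if len(above) == 0:
        raise ValueError("no bins exceed the provisional noise floor; "
                         "cannot locate a signal trend")
    hi = float(ur[above[-1]])
    hi = min(hi, noise_lo)  # never let the signal range touch the noise range
    lo = hi / 10.0
    in_range = (ur >= lo) & (ur <= hi)
    if in_range.sum() < 2:
        raise ValueError("heuristic signal range holds fewer than 2 bins")
    return FitRanges(lo, hi, noise_lo, noise_hi)


def analyze_profile(
    profile: RadialProfile,
    ranges: FitRanges,
    snr_res: float = 5.0,
    element: str = "",
) -> PowerLawFit:
    """Fit signal law and noise floor on one profile; derive the resolution.

    A non-negative fitted exponent marks the result invalid (NaN derived
    frequencies) instead of raising, so batch runs over many elements can
    complete; a u_res beyond the profile's frequency band sets
    ``out_of_band``.
    """
    P, a = fit_signal(profile, ranges)
    S_nf = estimate_noise_floor(profile, ranges)
    if a >= 0 or S_nf <= 0:
        warnings.warn(
            f"fit for {element or 'profile'} is invalid "
            f"(a={a:.3g}, S_nf={S_nf:.3g}); no decaying signal trend"
        )
        return PowerLawFit(P, a, S_nf, snr_res, float("nan"), float("nan"),
                           float("nan"), ranges, profile.sector, element,
                           valid=False)
    u_knee = knee_frequency(P, a, S_nf)
    u_res, delta_res = resolution(P, a, S_nf, snr_res)
    out_of_band = bool(u_res > profile.ur_max)
    if out_of_band:
        warnings.warn(
            f"u_res={u_res:.4g}/um exceeds the profile band "
            f"(max {profile.ur_max:.4g}/um); resolution is optic-limited"
        )
    return PowerLawFit(P, a, S_nf, snr_res, u_knee, u_res, delta_res,
                       ranges, profile.sector, element, out_of_band=out_of_band)


def analyze_map(
    emap: ElementalMap,
    ranges: FitRanges | None = None,
    sector: SectorSpec | None = None,
    n_bins: int | None = None,
    snr_res: float = 5.0,
) -> PowerLawFit:
    """Full single-image resolution estimate for one elemental map.

    Runs exit wave -> padding -> PSD -> radial profile -> fit.  When
    ``ranges`` is omitted the heuristic of :func:`suggest_ranges` is used.
    """
    from .psd import map_psd_profile

    profile = map_psd_profile(emap, n_bins=n_bins, sector=sector)
    if ranges is None:
        ranges = suggest_ranges(profile)
    return analyze_profile(profile, ranges, snr_res=snr_res, element=emap.element)
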