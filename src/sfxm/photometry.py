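"""Closed-form photometry for scanning-microprobe beamline characterization.

Unit policy: detector geometry in millimeters, resolutions in micrometers,
preamplifier gain sensitivity in uA/V at the interface (converted to pA/V
internally), photon fluxes in photons/s.  Every function documents its units
and validates its inputs, so dimensional mistakes fail loudly rather than
silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from scipy.optimize import least_squares

PA_PER_UA = 1.0e6  # picoamps per microamp


@dataclass
class PhotometrySettings:
    """Scalar beamline/detector settings for the photometry calculators.

    Attributes
    ----------
    K_E : float
        Photodiode flux-to-photocurrent conversion, photons/(pA s).
    g_s : float
        Preamplifier gain sensitivity, uA/V.
    V_out : float
        Photodiode voltage, V.
    A_active : float
        Fluorescence-detector active area, mm^2.
    d_sd : float
        Sample-to-detector distance, mm.
    theta : float
        Sample/scan-stage tilt from normal incidence, degrees.
    Phi : float
        Focused photon flux, photons/s (measured or from photon_flux).
    delta_x, delta_y : float
        Directional spatial resolutions of the probe, um.
    """

    K_E: float | None = None
    g_s: float | None = None
    V_out: float | None = None
    A_active: float | None = None
    d_sd: float | None = None
    theta: float | None = None
    Phi: float | None = None
    delta_x: float | None = None
    delta_y: float | None = None

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PhotometrySettings":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown photometry settings: {sorted(unknown)}")
        return cls(**d)

    def require(self, *names: str) -> list[float]:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(f"missing photometry settings: {missing}")
        return [float(getattr(self, n)) for n in names]


@dataclass
class DistanceFitResult:
    """Inverse-square fit of fluorescence intensity vs detector displacement."""

    alpha: float      # intensity * mm^2
    d_sd: float       # mm
    residual: float   # sum of squared residuals


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


def photon_flux(K_E: float, g_s: float, V_out: float) -> float:
    """Absolute photon flux from a calibrated photodiode reading.

    Phi = K_E * g_s * V_out with K_E in photons/(pA s), g_s in uA/V
    (converted to pA/V internally) and V_out in volts; dark-current voltage
    is assumed negligible.  Returns photons/s.  V_out = 0 gives 0.
    """
    _check_positive(K_E=K_E, g_s=g_s)
    if V_out < 0:
        raise ValueError(f"V_out must be non-negative, got {V_out}")
    return K_E * (g_s * PA_PER_UA) * V_out


def effective_beam_width(W_beam: float, theta: float) -> float:
    """Beam width along the scan direction of a sample tilted by theta degrees.

    W' = W_beam / cos(theta); theta must satisfy 0 <= theta < 90.
    """
    _check_positive(W_beam=W_beam)
    if not (0.0 <= theta < 90.0):
        raise ValueError(f"tilt must satisfy 0 <= theta < 90 degrees, got {theta}")
    return W_beam / np.cos(np.radians(theta))


def fit_detector_distance(
    displacements: Sequence[float],
    intensities: Sequence[float],
) -> DistanceFitResult:
    """Fit I(dd) = alpha / (d_sd + dd)^2 for the sample-to-detector distance.

    ``displacements`` are detector offsets dd in mm (e.g. 0, 3, 6);
    ``intensities`` are fluorescence intensities already normalized for
    incident-flux variation.  Deterministic initialization:
    alpha0 = I(dd_min) * (dd_max - dd_min + 10)^2, d0 = 10 mm, with both
    parameters bounded positive.
    """
    dd = np.asarray(displacements, dtype=np.float64)
    inten = np.asarray(intensities, dtype=np.float64)
    if dd.shape != inten.shape or dd.ndim != 1:
        raise ValueError("displacements and intensities must be 1D and equal length")
    if len(dd) < 2 or len(np.unique(dd)) < 2:
        raise ValueError("need at least 2 distinct displacements")
    if np.any(inten <= 0):
        raise ValueError("intensities must be positive")

    i_min = int(np.argmin(dd))
    alpha0 = inten[i_min] * (dd.max() - dd.min() + 10.0) ** 2
    x0 = np.array([alpha0, 10.0])

    def resid(p: np.ndarray) -> np.ndarray:
        alpha, d_sd = p
        return alpha / (d_sd + dd) ** 2 - inten

    sol = least_squares(resid, x0, bounds=([1e-300, 1e-6], [np.inf, np.inf]),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    return DistanceFitResult(alpha=float(sol.x[0]), d_sd=float(sol.x[1]),
                             residual=float(2.0 * sol.cost))


def solid_angle(A_active: float, d_sd: float) -> float:
    """Detector collection solid angle Omega = A_active / d_sd^2, steradians.

    A_active in mm^2, d_sd in mm (planar-detector small-angle form).
    """
    _check_positive(A_active=A_active, d_sd=d_sd)
    return A_active / d_sd**2


def probe_area(delta_x: float, delta_y: float) -> float:
    """Probe area A = pi * delta_x * delta_y, um^2.

    Treats the directional resolutions as the radii of the first minimum of
    an Airy-like probe.
    """
    _check_positive(delta_x=delta_x, delta_y=delta_y)
    return np.pi * delta_x * delta_y


def fluence_rate(Phi: float, delta_x: float, delta_y: float) -> float:
    """Fluence per time dF/dt = Phi / (pi delta_x delta_y), photons/(um^2 s)."""
    _check_positive(Phi=Phi)
    return Phi / probe_area(delta_x, delta_y)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report display only)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def photometry_report(settings: PhotometrySettings) -> dict[str, float]:
    """Evaluate every calculator the settings support; full-precision values.

    Keys are produced only for quantities whose inputs are present; an empty
    settings object raises with the list of missing fields.
    """
    out: dict[str, float] = {}
    if all(getattr(settings, n) is not None for n in ("K_E", "g_s", "V_out")):
        out["photon_flux_per_s"] = photon_flux(*settings.require("K_E", "g_s", "V_out"))
    if all(getattr(settings, n) is not None for n in ("A_active", "d_sd")):
        out["solid_angle_sr"] = solid_angle(*settings.require("A_active", "d_sd"))
    phi = settings.Phi if settings.Phi is not None else out.get("photon_flux_per_s")
    if phi is not None and settings.delta_x is not None and settings.delta_y is not None:
        out["probe_area_um2"] = probe_area(settings.delta_x, settings.delta_y)
        out["fluence_rate_per_um2_s"] = fluence_rate(
            phi, settings.delta_x, settings.delta_y)
    if settings.theta is not None:
        out["beam_broadening_factor"] = effective_beam_width(1.0, settings.theta)
    if not out:
        raise ValueError(
            "no photometry quantity computable; provide at least one of "
            "(K_E, g_s, V_out), (A_active, d_sd), (Phi, delta_x, delta_y), theta"
        )
    return out
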