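"""Lamellar repeat distance (d-spacing) from fitted Bragg-peak positions.

Peak positions are converted to scattering vectors q_z = 4*pi*sin(theta)/lambda
and the repeat distance follows from the slope of q vs diffraction order
(d = 2*pi/slope), or from a single first-order reflection (d = 2*pi/q_1).
The d-spacing uncertainty is propagated from the slope uncertainty of the
weighted linear fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError, InputError
from .reduction import BraggPeak, BraggPeakSet

__all__ = ["LamellarFit", "q_from_theta", "theta_from_q", "dspacing_linear", "dspacing_single"]

#: Incident wavelength of the diffractometer used throughout (Angstrom).
DEFAULT_WAVELENGTH = 4.487


@dataclass
class LamellarFit:
    """Result of a d-spacing determination."""

    d_spacing: float
    sigma_d: float
    slope_q_per_order: float
    slope_err: float
    intercept_q: float
    intercept_err: float
    n_orders_used: int
    method: str  # "linear_fit" | "single_peak"
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.d_spacing <= 0:
            raise InputError("d-spacing must be positive")
        if self.method not in ("linear_fit", "single_peak"):
            raise InputError(f"unknown method {self.method!r}")
        if (self.method == "single_peak") != (self.n_orders_used == 1):
            raise InputError("method single_peak iff exactly one order used")

    def to_dict(self):
        return {
            "d_spacing_A": self.d_spacing,
            "sigma_d_A": self.sigma_d,
            "slope_q_per_order": self.slope_q_per_order,
            "intercept_q": self.intercept_q,
            "n_orders_used": self.n_orders_used,
            "method": self.method,
            "flags": list(self.flags),
        }


def q_from_theta(two_theta_deg, wavelength: float = DEFAULT_WAVELENGTH):
    """Scattering vector q_z (1/Angstrom) from 2theta (deg): 4*pi*sin(theta)/lambda."""
    two_theta_deg = np.asarray(two_theta_deg, dtype=float)
    if np.any(two_theta_deg <= 0) or np.any(two_theta_deg >= 180):
        raise GeometryError("2theta must lie in (0, 180) degrees")
    if wavelength <= 0:
        raise GeometryError("wavelength must be positive")
    q = 4 * np.pi * np.sin(np.radians(two_theta_deg / 2)) / wavelength
    return float(q) if q.ndim == 0 else q


def theta_from_q(q, wavelength: float = DEFAULT_WAVELENGTH):
    """Inverse of :func:`q_from_theta`: 2theta (deg) for a given q_z (1/Angstrom)."""
    q = np.asarray(q, dtype=float)
    s = q * wavelength / (4 * np.pi)
    if np.any(s <= 0) or np.any(s >= 1):
        raise GeometryError("q outside the accessible range for this wavelength")
    tt = 2 * np.degrees(np.arcsin(s))
    return float(tt) if tt.ndim == 0 else tt


def _sigma_q(peak: BraggPeak, wavelength: float) -> float:
    # dq/d(2theta) = (2 pi / lambda) cos(theta), with 2theta in radians
    th = np.radians(peak.position_2theta / 2)
    return 2 * np.pi / wavelength * np.cos(th) * np.radians(peak.position_err)


def dspacing_linear(peaks: BraggPeakSet, wavelength: float = DEFAULT_WAVELENGTH) -> LamellarFit:
    """Weighted linear fit of q_h vs order h; d = 2*pi/slope.

    Inverse-variance weights from fitted position uncertainties (unweighted
    fallback when absent). The intercept is left free to absorb zero-angle
    misalignment and is flagged when it differs from 0 by more than 3 sigma.
    Peaks flagged non-lamellar are excluded.
    """
    usable = [p for p in peaks if not p.non_lamellar]
    if len(usable) < 2:
        raise InputError(
            "need >= 2 lamellar orders for a linear fit; use dspacing_single"
        )
    h = np.array([p.order_h for p in usable], dtype=float)
    q = np.array([q_from_theta(p.position_2theta, wavelength) for p in usable])
    sq = np.array([_sigma_q(p, wavelength) for p in usable])

    weighted = np.all(sq > 0)
    w = 1.0 / sq**2 if weighted else np.ones_like(q)

    S = w.sum()
    Sx = (w * h).sum()
    Sy = (w * q).sum()
    Sxx = (w * h * h).sum()
    Sxy = (w * h * q).sum()
    delta = S * Sxx - Sx**2
    slope = (S * Sxy - Sx * Sy) / delta
    intercept = (Sxx * Sy - Sx * Sxy) / delta

    if weighted:
        var_slope = S / delta
        var_intercept = Sxx / delta
    else:
        resid = q - (slope * h + intercept)
        dof = len(usable) - 2
        s2 = float((w * resid**2).sum() / dof) if dof > 0 else 0.0
        var_slope = s2 * S / delta
        var_intercept = s2 * Sxx / delta

    if slope <= 0:
        raise InputError(f"non-positive q-vs-order slope ({slope:.3g})")

    d = 2 * np.pi / slope
    sigma_d = 2 * np.pi * np.sqrt(var_slope) / slope**2

    flags = []
    sig_b = np.sqrt(var_intercept)
    if sig_b > 0 and abs(intercept) > 3 * sig_b:
        flags.append("intercept_significant")
    if len(usable) < len(peaks):
        flags.append("non_lamellar_peaks_excluded")

    return LamellarFit(
        d_spacing=float(d),
        sigma_d=float(sigma_d),
        slope_q_per_order=float(slope),
        slope_err=float(np.sqrt(var_slope)),
        intercept_q=float(intercept),
        intercept_err=float(sig_b),
        n_orders_used=len(usable),
        method="linear_fit",
        flags=flags,
    )


def dspacing_single(peak: BraggPeak, wavelength: float = DEFAULT_WAVELENGTH) -> LamellarFit:
    """Single-reflection rule d = 2*pi/q_z, assuming the peak is first order."""
    q1 = q_from_theta(peak.position_2theta, wavelength)
    if q1 <= 0:
        raise InputError("non-positive scattering vector")
    d = 2 * np.pi / q1
    sq = _sigma_q(peak, wavelength)
    sigma_d = 2 * np.pi * sq / q1**2
    return LamellarFit(
        d_spacing=float(d),
        sigma_d=float(sigma_d),
        slope_q_per_order=float(q1),
        slope_err=float(sq),
        intercept_q=0.0,
        intercept_err=0.0,
        n_orders_used=1,
        method="single_peak",
    )
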