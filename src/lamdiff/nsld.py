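"""Structure factors, intensity corrections, phasing and density synthesis.

Integrated Bragg intensities are corrected for absorption, the Lorentz
factor and the beam-footprint (flux) factor, giving structure-factor
amplitudes |F_h| = sqrt(I_h * C_abs * C_Lor * C_flux). For a centrosymmetric
stack each amplitude carries only a sign V_h; the sign vector is resolved by
enumerating all hypotheses and keeping those that place the density minimum
at the bilayer midplane and the maxima in the polar-head region. The
scattering-length density profile is then the cosine series

    rho(z) = (2/d) * sum_h V_h * |F_h| * cos(2 pi h z / d).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .exceptions import (
    GeometryError,
    InputError,
    InsufficientOrdersError,
    PhaseError,
)
from .reduction import BraggPeakSet

__all__ = [
    "CorrectionContext",
    "StructureFactorSet",
    "NSLDProfile",
    "absorption_correction",
    "lorentz_correction",
    "flux_correction",
    "correction_product",
    "structure_factor_amplitudes",
    "phase_search",
    "synthesize_profile",
    "structure_factors_from_profile",
    "water_profile_by_contrast",
]


@dataclass
class CorrectionContext:
    """Geometry entering the intensity corrections.

    mu_t is the dimensionless attenuation-thickness product; sample_length_L
    (mm) is the sample extent along the beam; beam_half_width_delta (mm) is
    half the beam width. ``flux_denominator`` selects the erf-argument
    normalization, sqrt(8)*delta ("sqrt8", default) or 8*delta ("eight").
    """

    mu_t: float = 0.0
    sample_length_L: float = 40.0
    beam_half_width_delta: float = 1.0
    wavelength: float = 4.487
    flux_denominator: str = "sqrt8"

    def __post_init__(self):
        if self.mu_t < 0:
            raise InputError("mu_t must be >= 0")
        if self.beam_half_width_delta <= 0 or self.sample_length_L <= 0:
            raise InputError("beam/sample geometry must be positive")
        if self.flux_denominator not in ("sqrt8", "eight"):
            raise InputError("flux_denominator must be 'sqrt8' or 'eight'")


@dataclass
class StructureFactorSet:
    """Amplitudes |F_h| (and, once phased, signs V_h) for orders 1..n."""

    d_spacing: float
    orders: np.ndarray
    amplitudes: np.ndarray
    amplitude_err: np.ndarray = None
    signs: np.ndarray = None  # None until phased
    missing_orders: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.orders = np.asarray(self.orders, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.d_spacing <= 0:
            raise InputError("d-spacing must be positive")
        if not np.array_equal(self.orders, np.arange(1, self.orders.size + 1)):
            raise InputError("orders must be contiguous from 1 (record gaps as missing)")
        if np.any(self.amplitudes < 0):
            raise InputError("structure-factor amplitudes must be >= 0")
        if self.amplitude_err is None:
            self.amplitude_err = np.zeros_like(self.amplitudes)
        else:
            self.amplitude_err = np.asarray(self.amplitude_err, dtype=float)
        if self.signs is not None:
            self.signs = np.asarray(self.signs, dtype=int)
            if self.signs.size != self.amplitudes.size or np.any(np.abs(self.signs) != 1):
                raise PhaseError("signs must be +/-1 for every order")

    @property
    def n_orders(self) -> int:
        return int(self.orders.size)

    def signed(self) -> np.ndarray:
        if self.signs is None:
            raise PhaseError("structure factors are unphased")
        return self.signs * self.amplitudes

    def with_signs(self, signs) -> "StructureFactorSet":
        return StructureFactorSet(
            d_spacing=self.d_spacing,
            orders=self.orders.copy(),
            amplitudes=self.amplitudes.copy(),
            amplitude_err=self.amplitude_err.copy(),
            signs=np.asarray(signs, dtype=int),
            missing_orders=list(self.missing_orders),
            metadata=dict(self.metadata),
        )


@dataclass
class NSLDProfile:
    """Periodic, centrosymmetric density rho(z) over one repeat distance.

    z_grid spans [-d/2, +d/2) uniformly; rho is in arbitrary units (no
    absolute scale is defined for these measurements).
    """

    z_grid: np.ndarray
    rho: np.ndarray
    d_spacing: float
    n_orders: int
    contrast_d2o: float = 0.08
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.z_grid.size != self.rho.size:
            raise InputError("z grid and rho must have equal length")
        dz = np.diff(self.z_grid)
        if not np.allclose(dz, dz[0], rtol=1e-9, atol=1e-12):
            raise InputError("z grid must be uniform")
        scale = np.max(np.abs(self.rho))
        if scale > 0:
            # even-function check; index 0 (z = -d/2) has no mirror on the grid
            odd = np.max(np.abs(self.rho[1:] - self.rho[1:][::-1]))
            if odd > 1e-6 * scale:
                raise InputError("profile is not even within tolerance")

    @property
    def dz(self) -> float:
        return float(self.z_grid[1] - self.z_grid[0])

    def normalized(self) -> "NSLDProfile":
        """Copy scaled to max|rho| = 1 (for cross-condition overlays)."""
        scale = np.max(np.abs(self.rho))
        rho = self.rho / scale if scale > 0 else self.rho.copy()
        return NSLDProfile(
            self.z_grid.copy(), rho, self.d_spacing, self.n_orders,
            self.contrast_d2o, dict(self.metadata),
        )

    def rho_at(self, z) -> np.ndarray:
        """Evaluate the band-limited series at arbitrary z (requires signs in metadata)."""
        return np.interp(np.asarray(z, float), self.z_grid, self.rho)


def _check_theta(theta_deg):
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(theta <= 0) or np.any(theta >= 90):
        raise GeometryError("theta must lie in (0, 90) degrees")
    return np.radians(theta)


def absorption_correction(ctx: CorrectionContext, theta_deg) -> np.ndarray:
    """C_abs = alpha / (1 - exp(-alpha)) with alpha = 2*mu_t/sin(theta).

    Always >= 1; the alpha -> 0 limit is handled explicitly (C_abs -> 1).
    """
    th = _check_theta(theta_deg)
    alpha = 2.0 * ctx.mu_t / np.sin(th)
    out = np.where(
        alpha < 1e-12, 1.0, alpha / -np.expm1(-np.where(alpha < 1e-12, 1.0, alpha))
    )
    return float(out) if out.ndim == 0 else out


def lorentz_correction(theta_deg) -> np.ndarray:
    """C_Lor = sin(2*theta)."""
    th = _check_theta(theta_deg)
    out = np.sin(2 * th)
    return float(out) if out.ndim == 0 else out


def flux_correction(ctx: CorrectionContext, theta_deg) -> np.ndarray:
    """C_flux = 1/erf(L*sin(theta) / (sqrt(8)*delta)); >= 1.

    Accounts for the beam overfilling the sample footprint at small angles
    (Gaussian beam of full width 2*delta).
    """
    th = _check_theta(theta_deg)
    denom = (
        np.sqrt(8.0) * ctx.beam_half_width_delta
        if ctx.flux_denominator == "sqrt8"
        else 8.0 * ctx.beam_half_width_delta
    )
    arg = ctx.sample_length_L * np.sin(th) / denom
    e = erf(arg)
    if np.any(e < 1e-12):
        raise GeometryError(
            "beam footprint vastly overfills the sample (erf underflow); "
            "check sample_length_L and beam_half_width_delta"
        )
    out = 1.0 / e
    return float(out) if out.ndim == 0 else out


def correction_product(ctx: CorrectionContext, theta_deg) -> np.ndarray:
    """C_abs * C_Lor * C_flux at theta (deg)."""
    return (
        absorption_correction(ctx, theta_deg)
        * lorentz_correction(theta_deg)
        * flux_correction(ctx, theta_deg)
    )


def structure_factor_amplitudes(
    peaks: BraggPeakSet, ctx: CorrectionContext, d_spacing: float
) -> StructureFactorSet:
    """|F_h| = sqrt(I_h * C_abs * C_Lor * C_flux) per fitted order.

    Missing orders (gaps in the 1..h_max sequence) are recorded with
    amplitude 0 and flagged; uncertainties propagate as
    sigma_F = sigma_I * |F| / (2 I).
    """
    if d_spacing <= 0:
        raise InputError("d-spacing must be positive")
    by_order = {}
    for p in peaks:
        if p.integrated_intensity < 0:
            raise InputError(f"negative integrated intensity for order {p.order_h}")
        by_order[p.order_h] = p
    h_max = max(by_order)
    amps = np.zeros(h_max)
    errs = np.zeros(h_max)
    missing = []
    for h in range(1, h_max + 1):
        if h not in by_order:
            missing.append(h)
            continue
        p = by_order[h]
        corr = correction_product(ctx, p.position_2theta / 2.0)
        F = np.sqrt(p.integrated_intensity * corr)
        amps[h - 1] = F
        if p.integrated_intensity > 0:
            errs[h - 1] = p.intensity_err * F / (2 * p.integrated_intensity)
    if missing:
        warnings.warn(
            f"orders {missing} missing; amplitudes set to 0 (affects d_b accuracy)",
            stacklevel=2,
        )
    return StructureFactorSet(
        d_spacing=float(d_spacing),
        orders=np.arange(1, h_max + 1),
        amplitudes=amps,
        amplitude_err=errs,
        missing_orders=missing,
        metadata=dict(peaks.metadata),
    )


def synthesize_profile(sf: StructureFactorSet, n_grid: int = 512) -> NSLDProfile:
    """Cosine synthesis rho(z) = (2/d) sum_h V_h |F_h| cos(2 pi h z / d)."""
    if sf.signs is None:
        raise PhaseError("cannot synthesize an unphased structure-factor set")
    if n_grid < 64:
        raise InputError("n_grid must be >= 64")
    d = sf.d_spacing
    z = d * (np.arange(n_grid) / n_grid - 0.5)
    signed = sf.signed()
    rho = np.zeros(n_grid)
    for h, F in zip(sf.orders, signed):
        rho += F * np.cos(2 * np.pi * h * z / d)
    rho *= 2.0 / d
    return NSLDProfile(
        z_grid=z,
        rho=rho,
        d_spacing=d,
        n_orders=sf.n_orders,
        contrast_d2o=sf.metadata.get("d2o_fraction", 0.08),
        metadata={"signs": [int(s) for s in sf.signs], **sf.metadata},
    )


def structure_factors_from_profile(
    profile, n_orders: int, odd_tol: float = 1e-6
) -> StructureFactorSet:
    """Cosine moments F_h = integral rho(z) cos(2 pi h z / d) dz, h = 1..n.

    Uses the Riemann sum on the uniform periodic grid, which is exactly
    orthogonal to the synthesis above (round trips to ~1e-15). Rejects
    profiles with an odd component beyond tolerance: the cosine-only model
    is invalid for asymmetric densities.
    """
    z = np.asarray(profile.z_grid, dtype=float)
    rho = np.asarray(profile.rho, dtype=float)
    d = profile.d_spacing
    scale = np.max(np.abs(rho))
    if scale > 0:
        odd = np.max(np.abs(rho[1:] - rho[1:][::-1]))
        if odd > odd_tol * scale:
            raise InputError("profile has an odd component; cosine model invalid")
    if n_orders < 1 or n_orders >= z.size // 2:
        raise InputError("n_orders must satisfy 1 <= n < n_grid/2")
    dz = z[1] - z[0]
    h = np.arange(1, n_orders + 1)
    cosmat = np.cos(2 * np.pi * np.outer(h, z) / d)
    F = cosmat @ rho * dz
    signs = np.where(F >= 0, 1, -1).astype(int)
    return StructureFactorSet(
        d_spacing=float(d),
        orders=h,
        amplitudes=np.abs(F),
        signs=signs,
        metadata={"d2o_fraction": getattr(profile, "contrast_d2o", 0.08)},
    )


@dataclass
class PhaseCandidate:
    signs: tuple
    depth: float       # (max rho - rho(0)) / max|rho|, ranking key
    rho_center: float
    z_max_frac: float  # |z_max| / (d/2)


def phase_search(
    sf: StructureFactorSet,
    d_b_window=(0.5, 0.95),
    n_grid: int = 512,
) -> list:
    """Enumerate sign hypotheses; keep those consistent with a bilayer.

    The global sign is fixed by requiring rho(0) <= 0. A hypothesis passes
    when (a) the global minimum of the synthesized profile lies within
    |z| <= d/8 of the midplane and (b) the global maximum lies in the
    polar-head window |z|/(d/2) in ``d_b_window``. Passing vectors are
    ranked by the depth of the midplane minimum (scale-invariant), best
    first. Refuses sets with fewer than 3 nonzero orders: two diffraction
    orders do not provide sufficient resolution and can mislead.
    """
    nz = sf.amplitudes > 0
    if int(nz.sum()) < 3:
        raise InsufficientOrdersError(
            f"only {int(nz.sum())} nonzero orders; >= 3 required for a "
            "meaningful centrosymmetric phase assignment"
        )
    d = sf.d_spacing
    n = sf.n_orders
    z = d * (np.arange(n_grid) / n_grid - 0.5)
    basis = np.cos(2 * np.pi * np.outer(sf.orders, z) / d)  # (n, n_grid)
    i0 = n_grid // 2  # z = 0
    half = d / 2

    candidates = []
    for signs in itertools.product((-1, 1), repeat=n):
        v = np.asarray(signs)
        rho = (2.0 / d) * (v * sf.amplitudes) @ basis
        if rho[i0] > 0:
            continue  # global-sign convention: midplane density <= 0
        i_min = int(np.argmin(rho))
        if abs(z[i_min]) > d / 8:
            continue
        i_max = int(np.argmax(rho))
        zfrac = abs(z[i_max]) / half
        if not (d_b_window[0] <= zfrac <= d_b_window[1]):
            continue
        scale = np.max(np.abs(rho))
        if scale == 0:
            continue
        depth = (rho[i_max] - rho[i0]) / scale
        candidates.append(
            PhaseCandidate(
                signs=tuple(int(s) for s in v),
                depth=float(depth),
                rho_center=float(rho[i0]),
                z_max_frac=float(zfrac),
            )
        )
    candidates.sort(key=lambda c: c.depth, reverse=True)
    return candidates


def water_profile_by_contrast(
    profile_100: NSLDProfile, profile_8: NSLDProfile, lipid_frac: float = 0.75
):
    """Water distribution as the scaled difference of two contrast profiles.

    The 100%-D2O profile is aligned to the 8% one by least squares over the
    lipid region |z| <= lipid_frac * d/2 (water there is negligible), then
    subtracted. Returns (z_grid, water_curve, scale_applied).
    """
    if abs(profile_100.d_spacing - profile_8.d_spacing) > 0.01 * profile_8.d_spacing:
        raise InputError(
            "contrast pair has mismatched d-spacings "
            f"({profile_100.d_spacing:.2f} vs {profile_8.d_spacing:.2f} A)"
        )
    z = profile_8.z_grid
    rho8 = profile_8.rho
    rho100 = profile_100.rho
    if profile_100.z_grid.size != z.size:
        rho100 = np.interp(z, profile_100.z_grid, profile_100.rho)
    mask = np.abs(z) <= lipid_frac * profile_8.d_spacing / 2
    denom = float(np.dot(rho8[mask], rho8[mask]))
    scale = float(np.dot(rho100[mask], rho8[mask]) / denom) if denom > 0 else 1.0
    water = rho100 - scale * rho8
    return z.copy(), water, scale
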