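"""Forward simulator: parametric membrane density profiles -> noisy diffraction.

Ground-truth scattering-length density profiles are built as sums of
mirrored Gaussian components (headgroups, CH2, CH3, water), band-limited to
a chosen number of diffraction orders, converted to integrated Bragg
intensities by inverting the analysis-side corrections, and rendered as 1D
diffractograms (optionally 2D rocking-scan maps) with Poisson counting
noise. Four sample archetypes are provided, parameterized by temperature,
relative humidity and D2O contrast through a packaged lookup table of
measured repeat distances and bilayer thicknesses; intermediate conditions
are linearly interpolated (a fixture convention, not a measurement claim).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError, InputError
from .lamellar import theta_from_q
from .nsld import (
    CorrectionContext,
    NSLDProfile,
    StructureFactorSet,
    correction_product,
    structure_factors_from_profile,
    synthesize_profile,
)
from .reduction import Diffractogram1D, ReciprocalMap

__all__ = [
    "GaussianComponent",
    "SampleCondition",
    "InstrumentConfig",
    "MembraneProfileSpec",
    "build_profile",
    "intensities_from_factors",
    "synth_diffractogram",
    "synth_omega_map",
    "fixture_preset",
    "PRESET_LABELS",
]

MOIETIES = ("water", "headgroup", "CH2", "CH3")


@dataclass
class GaussianComponent:
    """One mirrored-Gaussian density component.

    center_z >= 0; a component with center_z > 0 implies its mirror image at
    -center_z so the total profile is even. Amplitudes are in arbitrary
    density units (negative for aliphatic moieties at 8% D2O).
    """

    moiety: str
    center_z: float
    width_sigma: float
    amplitude: float

    def __post_init__(self):
        if self.moiety not in MOIETIES:
            raise InputError(f"unknown moiety {self.moiety!r}")
        if self.width_sigma <= 0:
            raise InputError(f"{self.moiety}: width_sigma must be positive")
        if self.center_z < 0:
            raise InputError(f"{self.moiety}: center_z must be >= 0 (mirroring is implicit)")


@dataclass
class SampleCondition:
    temperature_C: float = 70.0
    relative_humidity: float = 95.0
    d2o_fraction: float = 0.08

    def __post_init__(self):
        if not (0 <= self.d2o_fraction <= 1):
            raise InputError("d2o_fraction must be in [0, 1]")
        if not (0 < self.relative_humidity <= 100):
            raise InputError("relative_humidity must be in (0, 100]")

    def to_dict(self):
        return {
            "temperature_C": self.temperature_C,
            "relative_humidity": self.relative_humidity,
            "d2o_fraction": self.d2o_fraction,
        }


@dataclass
class InstrumentConfig:
    """Rendering and correction parameters of the diffractometer."""

    wavelength: float = 4.487
    mu_t: float = 0.05
    sample_length_L: float = 40.0
    beam_half_width_delta: float = 1.0
    peak_width_2theta: float = 0.25  # Gaussian sigma of rendered peaks, deg
    background_slope: float = 0.0   # counts per deg
    background_intercept: float = 0.0
    counts_scale: float = 1e5       # expected counts per unit intensity
    two_theta_min: float = 1.0
    two_theta_max: float = 25.0
    two_theta_step: float = 0.05
    omega_min: float = -1.0
    omega_max: float = 13.0
    omega_step: float = 0.05
    flux_denominator: str = "sqrt8"

    def __post_init__(self):
        if self.wavelength <= 0:
            raise InputError("wavelength must be positive")
        if self.mu_t < 0:
            raise InputError("mu_t must be >= 0")
        if self.beam_half_width_delta <= 0:
            raise InputError("beam_half_width_delta must be positive")

    def correction_context(self) -> CorrectionContext:
        return CorrectionContext(
            mu_t=self.mu_t,
            sample_length_L=self.sample_length_L,
            beam_half_width_delta=self.beam_half_width_delta,
            wavelength=self.wavelength,
            flux_denominator=self.flux_denominator,
        )

    def two_theta_grid(self) -> np.ndarray:
        n = int(round((self.two_theta_max - self.two_theta_min) / self.two_theta_step)) + 1
        return self.two_theta_min + self.two_theta_step * np.arange(n)

    def omega_grid(self) -> np.ndarray:
        n = int(round((self.omega_max - self.omega_min) / self.omega_step)) + 1
        return self.omega_min + self.omega_step * np.arange(n)

    def to_dict(self):
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class MembraneProfileSpec:
    """Ground-truth membrane description for the forward model."""

    period_d: float
    components: list
    n_orders: int = 4
    label: str = "custom"
    condition: SampleCondition = field(default_factory=SampleCondition)
    d_b_nominal: float = None  # bookkeeping for fixtures; not used by the model

    def __post_init__(self):
        if self.period_d <= 0:
            raise InputError("period_d must be positive")
        if not (1 <= self.n_orders <= 8):
            raise InputError("n_orders must be in 1..8")
        for c in self.components:
            if c.center_z >= self.period_d / 2:
                raise InputError(
                    f"component {c.moiety!r} centered at {c.center_z} A lies at or "
                    f"beyond the half-period {self.period_d / 2} A"
                )

    def to_dict(self):
        return {
            "period_d": self.period_d,
            "n_orders": self.n_orders,
            "label": self.label,
            "d_b_nominal": self.d_b_nominal,
            "condition": self.condition.to_dict(),
            "components": [
                {
                    "moiety": c.moiety,
                    "center_z": c.center_z,
                    "width_sigma": c.width_sigma,
                    "amplitude": c.amplitude,
                }
                for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, data) -> "MembraneProfileSpec":
        return cls(
            period_d=float(data["period_d"]),
            components=[GaussianComponent(**c) for c in data["components"]],
            n_orders=int(data["n_orders"]),
            label=data.get("label", "custom"),
            condition=SampleCondition(**data.get("condition", {})),
            d_b_nominal=data.get("d_b_nominal"),
        )


def _periodic_gaussian(z, center, sigma, amplitude, d, n_images=3):
    """Gaussian periodized over the repeat distance (images at center + k*d)."""
    out = np.zeros_like(z)
    for k in range(-n_images, n_images + 1):
        out += amplitude * np.exp(-0.5 * ((z - center - k * d) / sigma) ** 2)
    return out


def build_profile(spec: MembraneProfileSpec, n_grid: int = 512) -> NSLDProfile:
    """Sample the component-sum density on a uniform grid over [-d/2, +d/2).

    Each component contributes its Gaussian and (for center_z > 0) the
    mirror image, both periodized, so the result is even and periodic to
    round-off.
    """
    if n_grid < 64:
        raise InputError("n_grid must be >= 64")
    d = spec.period_d
    z = d * (np.arange(n_grid) / n_grid - 0.5)
    rho = np.zeros(n_grid)
    for c in spec.components:
        rho += _periodic_gaussian(z, c.center_z, c.width_sigma, c.amplitude, d)
        if c.center_z > 0:
            rho += _periodic_gaussian(z, -c.center_z, c.width_sigma, c.amplitude, d)
    return NSLDProfile(
        z_grid=z,
        rho=rho,
        d_spacing=d,
        n_orders=spec.n_orders,
        contrast_d2o=spec.condition.d2o_fraction,
        metadata={"label": spec.label, "ground_truth": True},
    )


def intensities_from_factors(
    sf: StructureFactorSet, instrument: InstrumentConfig, peak_two_thetas
) -> np.ndarray:
    """Raw integrated intensities I_h = F_h^2 / (C_abs * C_Lor * C_flux).

    Exact inverse of the analysis-side amplitude extraction, so the round
    trip intensities -> amplitudes -> intensities is algebraically exact.
    """
    peak_two_thetas = np.asarray(peak_two_thetas, dtype=float)
    if peak_two_thetas.size != sf.n_orders:
        raise InputError("need one peak position per order")
    if np.any(peak_two_thetas <= 0) or np.any(peak_two_thetas >= 180):
        raise GeometryError("peak 2theta outside (0, 180) degrees")
    ctx = instrument.correction_context()
    corr = np.array([correction_product(ctx, tt / 2.0) for tt in peak_two_thetas])
    return sf.amplitudes**2 / corr


def _peak_two_thetas(sf: StructureFactorSet, wavelength: float) -> np.ndarray:
    q = 2 * np.pi * sf.orders / sf.d_spacing
    return np.asarray(theta_from_q(q, wavelength))


def synth_diffractogram(
    sf: StructureFactorSet,
    instrument: InstrumentConfig,
    noise: str = "none",
    seed: int = 0,
) -> Diffractogram1D:
    """Render Gaussian Bragg peaks with areas I_h * counts_scale plus background.

    With ``noise="poisson"`` counts are drawn with the given seed; the
    counting-error column is sqrt(counts).
    """
    if noise not in ("none", "poisson"):
        raise InputError("noise must be 'none' or 'poisson'")
    tt = instrument.two_theta_grid()
    two_thetas = _peak_two_thetas(sf, instrument.wavelength)
    if np.any(two_thetas < tt[0]) or np.any(two_thetas > tt[-1]):
        raise GeometryError(
            "some diffraction orders fall outside the rendered 2theta range"
        )
    intensities = intensities_from_factors(sf, instrument, two_thetas)

    w = instrument.peak_width_2theta
    meta_warnings = []
    if two_thetas.size > 1 and np.any(np.diff(two_thetas) < 2 * w):
        meta_warnings.append("overlapping_orders")
        warnings.warn("rendered Bragg orders overlap (separation < 2x width)", stacklevel=2)

    ideal = instrument.background_slope * tt + instrument.background_intercept
    for I_h, c in zip(intensities, two_thetas):
        ideal += (
            I_h
            * instrument.counts_scale
            / (w * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * ((tt - c) / w) ** 2)
        )
    ideal = np.clip(ideal, 0, None)

    if noise == "poisson":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(ideal).astype(float)
    else:
        counts = ideal
    sigma = np.sqrt(np.maximum(counts, 1.0))  # counting error, floored at 1

    meta = {
        "label": sf.metadata.get("label", ""),
        "d_spacing_true": sf.d_spacing,
        "n_orders": sf.n_orders,
        "noise": noise,
        "seed": int(seed),
        "warnings": meta_warnings,
        "instrument": instrument.to_dict(),
        "peak_two_thetas": [float(t) for t in two_thetas],
        "true_intensities": [float(i) for i in intensities],
    }
    return Diffractogram1D(tt, counts, sigma, meta)


def synth_omega_map(
    sf: StructureFactorSet,
    instrument: InstrumentConfig,
    mosaic_sigma: float = 0.5,
    noise: str = "none",
    seed: int = 0,
) -> ReciprocalMap:
    """2D rocking map: each order is a Gaussian ridge in Omega at Omega = theta_h.

    Row-summing the map (``integrate_roi`` over the full scan) reproduces the
    paired 1D diffractogram exactly: each ridge profile is normalized to unit
    row sum and the background is spread uniformly over the Omega rows.
    """
    if mosaic_sigma <= 0:
        raise InputError("mosaic_sigma must be positive")
    diff = synth_diffractogram(sf, instrument, noise="none", seed=seed)
    tt = diff.two_theta_deg
    omega = instrument.omega_grid()
    two_thetas = np.asarray(diff.metadata["peak_two_thetas"])
    intensities = np.asarray(diff.metadata["true_intensities"])
    w = instrument.peak_width_2theta

    grid = np.zeros((omega.size, tt.size))
    bg = np.clip(
        instrument.background_slope * tt + instrument.background_intercept, 0, None
    )
    grid += bg[None, :] / omega.size
    for I_h, c in zip(intensities, two_thetas):
        ridge = np.exp(-0.5 * ((omega - c / 2.0) / mosaic_sigma) ** 2)
        s = ridge.sum()
        if s <= 0:
            raise GeometryError(
                f"mosaic ridge for the order at 2theta = {c:.2f} deg falls "
                "outside the Omega scan range"
            )
        ridge /= s
        curve = (
            I_h
            * instrument.counts_scale
            / (w * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * ((tt - c) / w) ** 2)
        )
        grid += np.outer(ridge, curve)

    if noise == "poisson":
        rng = np.random.default_rng(seed)
        grid = rng.poisson(grid).astype(float)
    elif noise != "none":
        raise InputError("noise must be 'none' or 'poisson'")

    meta = dict(diff.metadata)
    meta.update({"mosaic_sigma_deg": mosaic_sigma, "noise": noise, "seed": int(seed)})
    return ReciprocalMap(omega, tt, grid, meta)


# --------------------------------------------------------------------------
# Sample archetypes
#
# Repeat distances d and bilayer thicknesses d_b per (label, RH, T) transcribed
# from published per-condition measurements; entries between tabulated
# conditions are linear interpolations (fixture behavior only). Values in
# Angstrom; temperatures in Celsius.
# --------------------------------------------------------------------------

PRESET_LABELS = ("D", "T", "DT11", "DT21")

_TEMP_KNOTS = (60.0, 70.0, 80.0, 90.0)

# {label: {rh: {"d": (...), "d_b": (...)}}} over _TEMP_KNOTS
_CONDITION_TABLE = {
    "D": {
        80.0: {"d": (49.4, 49.6, 49.8, 49.8), "d_b": (39.0, 39.0, 39.0, 39.0)},
        95.0: {"d": (50.0, 48.5, 47.0, 47.0), "d_b": (39.0, 36.0, 36.0, 36.0)},
    },
    "T": {
        80.0: {"d": (51.0, 51.5, 51.0, 51.0), "d_b": (40.0, 40.5, 41.0, 41.0)},
        95.0: {"d": (56.0, 55.3, 56.0, 56.0), "d_b": (44.0, 44.0, 44.0, 44.0)},
    },
    "DT11": {
        80.0: {"d": (56.0, 56.0, 56.0, 56.0), "d_b": (44.0, 44.0, 44.0, 44.0)},
        95.0: {"d": (55.0, 55.3, 55.0, 55.0), "d_b": (43.0, 43.0, 42.5, 42.0)},
    },
    "DT21": {
        80.0: {"d": (55.0, 55.0, 55.0, 55.0), "d_b": (43.0, 43.0, 43.0, 43.0)},
        95.0: {"d": (54.0, 54.3, 54.0, 54.0), "d_b": (42.0, 41.5, 41.0, 41.0)},
    },
}

# Per-archetype component shapes (amplitudes relative to the tetraether
# headgroup = 1). Headgroup centers are placed at +/- d_b/2 and then
# calibrated so the band-limited head maxima land on d_b/2. The widths and
# CH2 centers were chosen so that, across the whole condition table, the
# constrained sign search ranks the generating sign vector first with a
# clear margin; they are fixture conventions, not measured quantities.
ARCHETYPE_SHAPES = {
    "D": {
        "head_amp": 0.20, "sigma_head": 3.4,
        "ch2_amp": 0.07, "ch2_center": 12.3, "sigma_ch2": 3.1,
        "ch3_amp": -0.05, "sigma_ch3": 2.3,
    },
    "T": {
        "head_amp": 1.00, "sigma_head": 3.8,
        "ch2_amp": 0.32, "ch2_center": 9.1, "sigma_ch2": 4.7,
        "ch3_amp": 0.0, "sigma_ch3": 2.3,
    },
    "DT11": {
        "head_amp": 0.80, "sigma_head": 3.97,
        "ch2_amp": 0.18, "ch2_center": 10.0, "sigma_ch2": 4.93,
        "ch3_amp": -0.09, "sigma_ch3": 1.95,
    },
    "DT21": {
        "head_amp": 0.65, "sigma_head": 2.74,
        "ch2_amp": 0.10, "ch2_center": 13.2, "sigma_ch2": 4.90,
        "ch3_amp": -0.15, "sigma_ch3": 2.42,
    },
}

SIGMA_WATER = 3.0
WATER_AMP_FULL = 1.2  # water amplitude at 100% D2O (arbitrary units)

_PRESET_CACHE: dict = {}  # (label, T, RH, d2o) -> calibrated head center


def _interp_knots(values, temperature):
    t = float(np.clip(temperature, _TEMP_KNOTS[0], _TEMP_KNOTS[-1]))
    return float(np.interp(t, _TEMP_KNOTS, values))


def _lookup_condition(label: str, condition: SampleCondition):
    table = _CONDITION_TABLE[label]
    rhs = sorted(table)
    rh = float(np.clip(condition.relative_humidity, rhs[0], rhs[-1]))
    d_by_rh = [_interp_knots(table[r]["d"], condition.temperature_C) for r in rhs]
    db_by_rh = [_interp_knots(table[r]["d_b"], condition.temperature_C) for r in rhs]
    d = float(np.interp(rh, rhs, d_by_rh))
    d_b = float(np.interp(rh, rhs, db_by_rh))
    return d, d_b


def _preset_orders(label: str, condition: SampleCondition) -> int:
    if label == "D":
        return 3 if condition.relative_humidity >= 90 else 2
    return 4


def _head_peak_halfwidth(spec: MembraneProfileSpec, n_grid: int = 1024) -> float:
    """Positive-z head-peak position of the band-limited spec profile."""
    profile = build_profile(spec, n_grid)
    sf = structure_factors_from_profile(profile, spec.n_orders)
    synth = synthesize_profile(sf, n_grid)
    z, rho = synth.z_grid, synth.rho
    pos = z > spec.period_d / 8
    i = np.flatnonzero(pos)[np.argmax(rho[pos])]
    if i == 0 or i == z.size - 1:
        return float(z[i])
    y0, y1, y2 = rho[i - 1], rho[i], rho[i + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    return float(z[i] + shift * synth.dz)


def _calibrate_head_center(make_spec, target: float, half_period: float) -> float:
    """Head center such that the band-limited head maximum lands on ``target``.

    The measured peak position is a discontinuous function of the center
    (the global maximum can jump between the head lobe and the inter-layer
    gap), so a coarse scan brackets the solution before bisection.
    """

    def err(a):
        return _head_peak_halfwidth(make_spec(a)) - target

    grid = target + np.linspace(-3.0, 3.0, 13)
    grid = grid[(grid > 0) & (grid < 0.49 * half_period * 2)]
    errors = np.array([err(a) for a in grid])
    k = int(np.argmin(np.abs(errors)))
    a_best, e_best = float(grid[k]), float(errors[k])
    # bisection against an adjacent point with opposite-sign error
    for j in (k - 1, k + 1):
        if 0 <= j < grid.size and errors[j] * e_best < 0:
            lo, hi = sorted((a_best, float(grid[j])))
            e_lo = err(lo)
            for _ in range(20):
                mid = 0.5 * (lo + hi)
                e_mid = err(mid)
                if abs(e_mid) < 5e-4:
                    return mid
                if e_lo * e_mid <= 0:
                    hi = mid
                else:
                    lo, e_lo = mid, e_mid
            return 0.5 * (lo + hi)
    return a_best


def _archetype_components(shape: dict, head_center: float, d: float,
                          condition: SampleCondition) -> list:
    comps = [
        GaussianComponent(
            "headgroup", head_center, shape["sigma_head"], shape["head_amp"]
        ),
    ]
    if shape["ch2_amp"] != 0.0:
        comps.append(
            GaussianComponent(
                "CH2", shape["ch2_center"], shape["sigma_ch2"], shape["ch2_amp"]
            )
        )
    if shape["ch3_amp"] != 0.0:
        comps.append(
            GaussianComponent("CH3", 0.0, shape["sigma_ch3"], shape["ch3_amp"])
        )
    water_amp = WATER_AMP_FULL * (condition.d2o_fraction - 0.08) / 0.92
    if abs(water_amp) > 1e-12:
        comps.append(
            GaussianComponent("water", 0.96 * d / 2, SIGMA_WATER, water_amp)
        )
    return comps


def fixture_preset(label: str, condition: SampleCondition = None) -> MembraneProfileSpec:
    """Documented ground-truth spec for one of the four sample archetypes.

    D: bilayer-forming diether with a CH3 midplane trough and weak headgroup
    signal (~0.2); T: membrane-spanning tetraether with a CH2 "hump" near
    |z| = 10 A, strong headgroups (1.0) and no midplane CH3; DT11/DT21: 1:1
    and 2:1 mixtures carrying both CH2 and CH3 components, the trough deeper
    in DT21. Periods and thicknesses come from the packaged condition table;
    the water component amplitude scales with D2O contrast and vanishes at
    the 8% null-water contrast.
    """
    if label not in PRESET_LABELS:
        raise InputError(f"unknown preset label {label!r}; expected one of {PRESET_LABELS}")
    condition = condition or SampleCondition()
    d, d_b = _lookup_condition(label, condition)
    n_orders = _preset_orders(label, condition)
    shape = ARCHETYPE_SHAPES[label]

    def make_spec(head_center):
        return MembraneProfileSpec(
            period_d=d,
            components=_archetype_components(shape, head_center, d, condition),
            n_orders=n_orders,
            label=label,
            condition=condition,
            d_b_nominal=d_b,
        )

    # membrane structure does not depend on the D2O contrast, so the head
    # center is calibrated once per (label, T, RH) on the null-water shape
    key = (label, condition.temperature_C, condition.relative_humidity)
    if key in _PRESET_CACHE:
        head_center = _PRESET_CACHE[key]
    elif n_orders >= 3:
        # calibrate the head-center so that the band-limited head maxima sit
        # at exactly +/- d_b/2 (truncation shifts peak positions slightly)
        null_condition = SampleCondition(
            condition.temperature_C, condition.relative_humidity, 0.08
        )
        spec_at = lambda a: MembraneProfileSpec(  # noqa: E731
            period_d=d,
            components=_archetype_components(shape, a, d, null_condition),
            n_orders=n_orders,
            label=label,
            condition=null_condition,
            d_b_nominal=d_b,
        )
        head_center = _calibrate_head_center(spec_at, d_b / 2, d / 2)
        _PRESET_CACHE[key] = head_center
    else:
        head_center = d_b / 2
        _PRESET_CACHE[key] = head_center
    return make_spec(head_center)
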