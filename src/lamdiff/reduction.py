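"""Reduction of rocking-scan maps to 1D diffractograms and Bragg-peak fitting.

A 2D reciprocal-space map (sample rotation Omega x scattering angle 2theta)
is reduced to a 1D intensity curve by summing rows inside a region of
interest; Bragg peaks are then located and fitted as Gaussians on a shared
linear background, giving integrated intensities with counting-statistics
uncertainties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from .exceptions import InputError, PeakFitError

__all__ = [
    "ReciprocalMap",
    "Diffractogram1D",
    "BraggPeak",
    "BraggPeakSet",
    "integrate_roi",
    "detect_peaks",
    "fit_peaks",
]


@dataclass
class ReciprocalMap:
    """Intensity grid over (Omega, 2theta), one row per Omega step."""

    omega_deg: np.ndarray
    two_theta_deg: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.omega_deg = np.asarray(self.omega_deg, dtype=float)
        self.two_theta_deg = np.asarray(self.two_theta_deg, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.omega_deg.size, self.two_theta_deg.size):
            raise InputError(
                f"intensity shape {self.intensity.shape} does not match axes "
                f"({self.omega_deg.size}, {self.two_theta_deg.size})"
            )
        if np.any(self.intensity < 0):
            raise InputError("reciprocal map intensities must be nonnegative")


@dataclass
class Diffractogram1D:
    """I vs 2theta curve with per-bin counting error."""

    two_theta_deg: np.ndarray
    counts: np.ndarray
    sigma: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.two_theta_deg = np.asarray(self.two_theta_deg, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = self.two_theta_deg.size
        if self.counts.size != n or self.sigma.size != n:
            raise InputError("two_theta, counts and sigma must have equal length")
        if np.any(np.diff(self.two_theta_deg) <= 0):
            raise InputError("two_theta axis must be strictly increasing")
        if np.any(self.counts < 0):
            raise InputError("counts must be nonnegative")
        if np.any(self.sigma[self.counts > 0] <= 0):
            raise InputError("sigma must be positive wherever counts > 0")


@dataclass
class BraggPeak:
    """One fitted lamellar reflection."""

    order_h: int
    position_2theta: float
    position_err: float
    integrated_intensity: float
    intensity_err: float
    width_2theta: float
    fit_quality: float = np.nan
    non_lamellar: bool = False

    def __post_init__(self):
        if self.order_h < 1:
            raise InputError("Bragg order must be >= 1")


@dataclass
class BraggPeakSet:
    """Fitted peaks of one diffractogram, ordered by ascending 2theta."""

    peaks: list
    reduced_chi2: float = np.nan
    background: tuple = (0.0, 0.0)  # (slope, intercept)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.position_2theta)
        pos = [p.position_2theta for p in self.peaks]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise InputError("peak positions must strictly increase with order")

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def orders(self):
        return [p.order_h for p in self.peaks]


def integrate_roi(rmap: ReciprocalMap, roi_omega=None) -> Diffractogram1D:
    """Sum map rows (Omega steps) inside the ROI into a 1D diffractogram.

    Parameters
    ----------
    rmap : ReciprocalMap
    roi_omega : (float, float), optional
        Inclusive Omega range in degrees; defaults to the full scan.

    The per-bin counting error is ``sqrt(summed counts)``; total counts
    inside the ROI are conserved exactly.
    """
    omega = rmap.omega_deg
    if roi_omega is None:
        mask = np.ones(omega.size, dtype=bool)
        roi_omega = (float(omega.min()), float(omega.max()))
    else:
        lo, hi = float(roi_omega[0]), float(roi_omega[1])
        if hi < lo:
            lo, hi = hi, lo
        if hi < omega.min() or lo > omega.max():
            raise InputError(
                f"ROI [{lo}, {hi}] deg outside scan range "
                f"[{omega.min()}, {omega.max()}] deg"
            )
        mask = (omega >= lo) & (omega <= hi)
        roi_omega = (lo, hi)
    if not mask.any():
        raise InputError("ROI selects no Omega rows")

    counts = rmap.intensity[mask].sum(axis=0)
    sigma = np.sqrt(counts)
    sigma[counts == 0] = 1.0  # counting-statistics convention for empty bins
    meta = dict(rmap.metadata)
    meta["roi_omega_deg"] = [roi_omega[0], roi_omega[1]]
    meta["n_omega_rows"] = int(mask.sum())
    return Diffractogram1D(rmap.two_theta_deg.copy(), counts, sigma, meta)


def detect_peaks(
    diff: Diffractogram1D,
    min_prominence: float = 5e-5,
    max_orders: int = 8,
    noise_sigmas: float = 5.0,
) -> list:
    """Locate candidate Bragg-peak positions (deg 2theta).

    Local maxima of the background-subtracted curve (rolling-median
    background) whose prominence exceeds both ``min_prominence`` times the
    largest excursion and ``noise_sigmas`` counting errors; at most
    ``max_orders`` candidates, sorted by 2theta. Bragg orders span decades
    in intensity, hence the permissive relative floor. An empty list is a
    valid result.
    """
    if diff.two_theta_deg.size < 16:
        raise InputError("diffractogram too short for peak detection (< 16 bins)")
    y = diff.counts
    win = max(5, (y.size // 16) | 1)
    background = ndimage.median_filter(y, size=win, mode="nearest")
    resid = y - background
    top = float(resid.max())
    if top <= 0:
        return []
    threshold = max(
        min_prominence * top, noise_sigmas * float(np.median(diff.sigma))
    )
    idx, props = signal.find_peaks(resid, prominence=threshold)
    if idx.size == 0:
        return []
    # keep the most prominent max_orders, then restore 2theta order
    keep = np.argsort(props["prominences"])[::-1][:max_orders]
    idx = np.sort(idx[keep])
    return [float(t) for t in diff.two_theta_deg[idx]]


def _assign_orders(positions_2theta) -> list:
    """Diffraction orders from peak positions, tolerating missing orders.

    The base spacing in sin(theta) is estimated from the smallest gap
    between consecutive peaks; each order is the rounded multiple. Falls
    back to rank assignment if the inference is inconsistent.
    """
    q = np.sin(np.radians(np.asarray(positions_2theta) / 2.0))
    n = q.size
    if n == 1:
        return [1]
    base = float(np.min(np.diff(q)))
    if base > 0:
        h = np.rint(q / base).astype(int)
        if h[0] >= 1 and np.all(np.diff(h) >= 1):
            return [int(x) for x in h]
    return list(range(1, n + 1))


def _multi_gauss(x, params, n_peaks):
    slope, intercept = params[0], params[1]
    y = slope * x + intercept
    for i in range(n_peaks):
        area, c, w = params[2 + 3 * i : 5 + 3 * i]
        y = y + area / (w * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - c) / w) ** 2)
    return y


def fit_peaks(
    diff: Diffractogram1D,
    candidates,
    width_guess: float = 0.3,
    max_order_gap_frac: float = 0.10,
) -> BraggPeakSet:
    """Simultaneous Gaussian + shared-linear-background fit of all peaks.

    Peaks are weighted by 1/sigma^2; returns positions, integrated areas,
    widths and covariance-derived uncertainties. Orders are assigned by rank
    of position; a peak whose position deviates more than
    ``max_order_gap_frac`` from the arithmetic progression implied by the
    others is flagged ``non_lamellar`` (excluded from d-spacing fits).
    Candidates closer than one width are merged before fitting.
    """
    cands = sorted(float(c) for c in candidates)
    if not cands:
        raise InputError("fit_peaks requires at least one candidate position")

    merged = [cands[0]]
    for c in cands[1:]:
        if c - merged[-1] < width_guess:
            merged[-1] = 0.5 * (merged[-1] + c)
            warnings.warn("merged candidate peaks closer than one width", stacklevel=2)
        else:
            merged.append(c)
    n = len(merged)

    x, y = diff.two_theta_deg, diff.counts
    sig = np.maximum(diff.sigma, 1.0)  # counting error is never below one count
    dx = float(np.median(np.diff(x)))

    # initial background from the curve edges
    b0 = 0.5 * (np.median(y[:5]) + np.median(y[-5:]))
    m0 = (np.median(y[-5:]) - np.median(y[:5])) / (x[-1] - x[0])
    p0 = [m0, b0]
    lo = [-np.inf, -np.inf]
    hi = [np.inf, np.inf]
    for c in merged:
        j = int(np.argmin(np.abs(x - c)))
        amp0 = max(y[j] - (m0 * c + b0), 1.0)
        p0 += [amp0 * width_guess * np.sqrt(2 * np.pi), c, width_guess]
        lo += [-np.inf, c - 5 * width_guess, 0.2 * dx]
        hi += [np.inf, c + 5 * width_guess, 20 * width_guess]

    def model(xx, *params):
        return _multi_gauss(xx, np.asarray(params), n)

    try:
        popt, pcov = optimize.curve_fit(
            model, x, y, p0=p0, sigma=sig, absolute_sigma=True,
            bounds=(lo, hi), maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        resid = y - model(x, *p0)
        raise PeakFitError(
            f"peak fit did not converge: {exc}",
            diagnostics={"rms_residual_at_p0": float(np.sqrt(np.mean(resid**2)))},
        ) from exc

    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    dof = max(x.size - popt.size, 1)
    chi2_red = float(np.sum(((y - model(x, *popt)) / sig) ** 2) / dof)

    rows = []
    for i in range(n):
        area, c, w = popt[2 + 3 * i : 5 + 3 * i]
        if area <= 0:
            warnings.warn(
                f"peak near {c:.2f} deg fitted with non-positive area; dropped",
                stacklevel=2,
            )
            continue
        rows.append((c, perr[3 + 3 * i], area, perr[2 + 3 * i], w))
    if not rows:
        raise PeakFitError("all fitted peaks had non-positive area")
    rows.sort()

    orders = _assign_orders([r[0] for r in rows])
    peaks = [
        BraggPeak(
            order_h=h,
            position_2theta=float(c),
            position_err=float(ce),
            integrated_intensity=float(a),
            intensity_err=float(ae),
            width_2theta=float(w),
            fit_quality=chi2_red,
        )
        for h, (c, ce, a, ae, w) in zip(orders, rows)
    ]

    # lamellar consistency: q_h / h should be common to all orders; with
    # fewer than 3 peaks there is no redundancy to identify an outlier
    if len(peaks) >= 3:
        th = np.radians([p.position_2theta / 2 for p in peaks])
        q = np.sin(th)  # proportional to q; wavelength cancels in the ratio
        ratio = q / np.array([p.order_h for p in peaks])
        ref = np.median(ratio)
        for p, r in zip(peaks, ratio):
            if abs(r - ref) > max_order_gap_frac * ref:
                p.non_lamellar = True
                warnings.warn(
                    f"peak at {p.position_2theta:.2f} deg off the lamellar "
                    "progression; flagged non-lamellar",
                    stacklevel=2,
                )

    return BraggPeakSet(
        peaks=peaks,
        reduced_chi2=chi2_red,
        background=(float(popt[0]), float(popt[1])),
        metadata=dict(diff.metadata),
    )
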