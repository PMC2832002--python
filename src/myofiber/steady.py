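"""Steady-state fitting: Hill force-pCa, phosphate dependence of k_F, and
fiber stiffness.

The force-Ca2+ relation is fitted with the Hill equation
``F = Fmax * Ca^n / (EC50^n + Ca^n)`` (Ca in µM), giving the maximal force
per cross-sectional area, the free Ca2+ for half-maximal force and the Hill
coefficient. The phosphate dependence of the force-redevelopment rate is
fitted with ``k_F = k1 + k_minus1*[Pi]/(K2+[Pi])``, whose three parameters
are the forward and reverse rates of the force-generating isomerization and
the Pi-release equilibrium constant. Stiffness is the ordinary-least-squares
slope of force change against length change over a set of small releases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .errors import DegenerateDataError, FitError, IdentifiabilityError

__all__ = [
    "HillFit",
    "PiFit",
    "StiffnessFit",
    "fit_hill",
    "fit_pi_dependence",
    "fit_stiffness",
    "relative_force",
    "elliptical_area",
]

#: upper bound on fitted rates (s^-1) and K2 (mM)
_RATE_BOUND = 500.0


@dataclass(frozen=True)
class HillFit:
    fmax: float  # mN/mm^2
    ec50: float  # µM
    n_hill: float
    fmax_se: float
    ec50_se: float
    n_hill_se: float
    n_points: int

    def __post_init__(self) -> None:
        if self.fmax <= 0 or self.ec50 <= 0 or self.n_hill <= 0:
            raise ValueError("fmax, ec50 and n_hill must be > 0")

    def predict(self, ca_uM: np.ndarray | float) -> np.ndarray | float:
        return hill(np.asarray(ca_uM, dtype=float), self.fmax, self.ec50, self.n_hill)


@dataclass(frozen=True)
class PiFit:
    k1: float  # s^-1
    k_minus1: float  # s^-1
    K2: float  # mM
    k1_se: float
    k_minus1_se: float
    K2_se: float
    n_points: int

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k_minus1 <= 0 or self.K2 <= 0:
            raise ValueError("k1, k_minus1 and K2 must be > 0")

    def predict(self, pi_mM: np.ndarray | float) -> np.ndarray | float:
        pi = np.asarray(pi_mM, dtype=float)
        return self.k1 + self.k_minus1 * pi / (self.K2 + pi)


@dataclass(frozen=True)
class StiffnessFit:
    slope: float  # mN/mm^2 per mm
    intercept: float  # mN/mm^2
    r2: float
    n_points: int


def hill(ca_uM: np.ndarray, fmax: float, ec50: float, n: float) -> np.ndarray:
    """Hill equation for force as a function of free Ca2+ (µM)."""
    ca = np.asarray(ca_uM, dtype=float)
    cn = ca**n
    return fmax * cn / (ec50**n + cn)


def _as_xy(points: Sequence[tuple[float, float]] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be a sequence of (x, y) pairs")
    return arr[:, 0], arr[:, 1]


def fit_hill(points: Sequence[tuple[float, float]], n_start: float = 2.0) -> HillFit:
    """Fit the Hill force-pCa relation to (free Ca2+ in µM, force) points.

    Requires at least four points spanning at least one decade of Ca2+ with
    genuine dynamic range in force; data sitting entirely near zero or near
    the plateau do not constrain EC50 and raise
    :class:`IdentifiabilityError`. By construction the returned curve equals
    ``fmax/2`` at ``ca = ec50``.
    """
    ca, f = _as_xy(points)
    if ca.size < 4:
        raise IdentifiabilityError("need at least 4 (Ca, force) points")
    if np.any(ca <= 0):
        raise ValueError("Ca2+ concentrations must be > 0")
    if np.max(ca) / np.min(ca) < 10.0:
        raise IdentifiabilityError("Ca2+ points must span at least one decade")
    fmax0 = float(np.max(f))
    if fmax0 <= 0 or float(np.ptp(f)) < 0.10 * fmax0:
        raise IdentifiabilityError(
            "forces show no dynamic range (all near zero or all near maximum)"
        )
    # EC50 seed: Ca2+ where force first crosses half of the largest force
    order = np.argsort(ca)
    ec50_0 = float(np.interp(0.5 * fmax0, f[order], ca[order]))
    if not np.isfinite(ec50_0) or ec50_0 <= 0:
        ec50_0 = float(np.sqrt(np.min(ca) * np.max(ca)))
    try:
        popt, pcov = curve_fit(
            hill,
            ca,
            f,
            p0=[fmax0, ec50_0, n_start],
            bounds=([1e-9, 1e-9, 0.1], [np.inf, np.inf, 20.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"Hill fit did not converge: {exc}") from exc
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    return HillFit(
        fmax=float(popt[0]),
        ec50=float(popt[1]),
        n_hill=float(popt[2]),
        fmax_se=float(se[0]),
        ec50_se=float(se[1]),
        n_hill_se=float(se[2]),
        n_points=int(ca.size),
    )


def _pi_relation(pi: np.ndarray, k1: float, km1: float, K2: float) -> np.ndarray:
    return k1 + km1 * pi / (K2 + pi)


def fit_pi_dependence(points: Sequence[tuple[float, float]]) -> PiFit:
    """Fit k_F = k1 + k_minus1*[Pi]/(K2+[Pi]) to ([Pi] in mM, k_F) points.

    k1 is anchored by the zero-Pi rate, k_minus1 by the saturating increment
    and K2 by the half-saturation phosphate concentration; fewer than three
    distinct Pi levels cannot separate the three parameters.
    """
    pi, kf = _as_xy(points)
    if np.any(pi < 0):
        raise ValueError("phosphate concentrations must be >= 0")
    n_distinct = np.unique(pi).size
    if n_distinct < 3:
        raise IdentifiabilityError(
            f"need at least 3 distinct Pi levels, got {n_distinct}"
        )
    if np.ptp(kf) == 0.0:
        raise DegenerateDataError("all k_F values are identical")
    k1_0 = float(np.mean(kf[pi == np.min(pi)]))
    km1_0 = max(float(np.mean(kf[pi == np.max(pi)])) - k1_0, 1.0)
    K2_0 = float(np.median(np.unique(pi)[1:])) if n_distinct > 1 else 10.0
    try:
        popt, pcov = curve_fit(
            _pi_relation,
            pi,
            kf,
            p0=[max(k1_0, 1e-3), km1_0, max(K2_0, 1e-3)],
            bounds=([1e-9, 1e-9, 1e-9], [_RATE_BOUND] * 3),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"Pi-dependence fit did not converge: {exc}") from exc
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    return PiFit(
        k1=float(popt[0]),
        k_minus1=float(popt[1]),
        K2=float(popt[2]),
        k1_se=float(se[0]),
        k_minus1_se=float(se[1]),
        K2_se=float(se[2]),
        n_points=int(pi.size),
    )


def fit_stiffness(points: Sequence[tuple[float, float]]) -> StiffnessFit:
    """Ordinary-least-squares line through (length change in mm, force
    change) release responses; the slope is reported as stiffness."""
    dl, df = _as_xy(points)
    if np.unique(dl).size < 2:
        raise IdentifiabilityError("need at least 2 distinct release amplitudes")
    res = linregress(dl, df)
    r2 = float(res.rvalue**2) if math.isfinite(res.rvalue) else 0.0
    return StiffnessFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        n_points=int(dl.size),
    )


def relative_force(f_at_pi: float, f_at_zero: float) -> float:
    """Force retained under added phosphate, as a percentage of the
    zero-added-Pi force."""
    if f_at_zero <= 0:
        raise ValueError("reference force must be > 0")
    return 100.0 * f_at_pi / f_at_zero


def elliptical_area(diameter1_mm: float, diameter2_mm: float) -> float:
    """Fiber cross-sectional area (mm^2) assuming an elliptical section,
    from two perpendicular diameters (mm)."""
    if diameter1_mm <= 0 or diameter2_mm <= 0:
        raise ValueError("diameters must be > 0")
    return math.pi * diameter1_mm * diameter2_mm / 4.0
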