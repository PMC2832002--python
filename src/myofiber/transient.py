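"""Single-exponential analysis of force transients.

Rate constants of force development (k_Act after caged-Ca2+ photolysis,
k_ATP after caged-ATP photolysis from Ca2+-rigor, k_F after a rapid length
release) are extracted by fitting

    F(t) = f_inf - (f_inf - f0) * exp(-rate * (t - t_start))

to the rising phase of the trace. For ATP-jump records the fit window starts
at the post-photolysis force trough (rigor crossbridges detach before cycling
bridges re-attach, producing a brief dip); for the other protocols the whole
record is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateDataError, FitError, WindowError
from .trace import ForceTrace

__all__ = ["ExpFit", "fit_single_exponential", "detect_fit_window", "fit_transient"]

#: fraction of the record searched for the ATP-jump force trough
_TROUGH_SEARCH_FRAC = 0.10
#: minimal force range (relative to max |force|) regarded as signal
_FLAT_REL_TOL = 1e-12


@dataclass(frozen=True)
class ExpFit:
    """Result of a single-exponential fit to a force transient."""

    rate: float  # s^-1
    f0: float  # force at window start, mN/mm^2
    f_inf: float  # asymptotic force, mN/mm^2
    window: tuple[float, float]  # (t_start, t_end), s
    r2: float
    protocol_kind: str = ""
    rate_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must precede window end")


def _mono_exp(t: np.ndarray, f0: float, f_inf: float, rate: float) -> np.ndarray:
    return f_inf - (f_inf - f0) * np.exp(-rate * t)


def _initial_guess(t: np.ndarray, f: np.ndarray) -> tuple[float, float, float]:
    """Rate seeded by log-linear regression of (f_inf_guess - F) against
    time, with the plateau guessed from the final 10% of samples."""
    f_inf = float(np.mean(f[-max(1, len(f) // 10):]))
    f0 = float(f[0])
    resid = f_inf - f if f_inf >= f0 else f - f_inf
    pos = resid > np.max(np.abs(resid)) * 1e-6
    if np.count_nonzero(pos) >= 3:
        slope = np.polyfit(t[pos], np.log(resid[pos]), 1)[0]
        rate = max(-slope, 1e-3)
    else:
        rate = 1.0 / max(t[-1] - t[0], 1e-6)
    return f0, f_inf, float(rate)


def fit_single_exponential(
    trace: ForceTrace, window: tuple[float, float] | None = None
) -> ExpFit:
    """Least-squares single-exponential fit inside a time window.

    Parameters are the initial force, the asymptotic force and the rate; all
    three are fitted (fixing the plateau at the final sample biases short
    records). Raises :class:`DegenerateDataError` for flat traces and
    :class:`FitError` on non-convergence.
    """
    if window is None:
        window = (float(trace.time_s[0]), float(trace.time_s[-1]))
    t_start, t_end = window
    mask = (trace.time_s >= t_start) & (trace.time_s <= t_end)
    t = trace.time_s[mask] - t_start
    f = trace.force[mask]
    if t.size < 10:
        raise FitError(f"fit window contains only {t.size} samples (need >= 10)")
    frange = float(np.ptp(f))
    if frange <= _FLAT_REL_TOL * max(1.0, float(np.max(np.abs(f)))):
        raise DegenerateDataError("force is constant inside the fit window")
    p0 = _initial_guess(t, f)
    try:
        popt, pcov = curve_fit(
            _mono_exp,
            t,
            f,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 1e5]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - depends on optimizer
        raise FitError(f"single-exponential fit did not converge: {exc}") from exc
    f0, f_inf, rate = (float(v) for v in popt)
    resid = f - _mono_exp(t, *popt)
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    rate_se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else float("nan")
    return ExpFit(
        rate=rate,
        f0=f0,
        f_inf=f_inf,
        window=(t_start, t_end),
        r2=r2,
        protocol_kind=trace.protocol_kind,
        rate_se=rate_se,
    )


def detect_fit_window(trace: ForceTrace) -> tuple[float, float]:
    """Protocol-aware fit-window selection.

    ATP-jump records are fitted from the force trough (global minimum within
    the first 10% of the record) to the end; all other protocols use the
    full record. A trace whose minimum falls on the final sample carries no
    rising phase and raises :class:`WindowError`.
    """
    if len(trace) < 50:
        raise WindowError(f"trace has only {len(trace)} samples (need >= 50)")
    if int(np.argmin(trace.force)) == len(trace) - 1:
        raise WindowError("force minimum at final sample: no rising phase to fit")
    t_end = float(trace.time_s[-1])
    if trace.protocol_kind == "ATP_JUMP":
        n_search = max(1, int(len(trace) * _TROUGH_SEARCH_FRAC))
        i_trough = int(np.argmin(trace.force[:n_search]))
        return (float(trace.time_s[i_trough]), t_end)
    return (float(trace.time_s[0]), t_end)


def fit_transient(trace: ForceTrace, window: tuple[float, float] | None = None) -> ExpFit:
    """Convenience wrapper: locate the window, then fit."""
    if window is None:
        window = detect_fit_window(trace)
    return fit_single_exponential(trace, window)
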