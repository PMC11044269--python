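"""Coordination-number autocorrelation, relaxation time, and decay-constant fits.

C_CN(t) is the normalized autocorrelation of the CN fluctuation
``dN(t) = N(t) - <N>``, estimated with the biased (1/N) autocovariance so
the resulting sequence is positive semidefinite, then normalized to
C(0) = 1.  The integral relaxation time tau_CN is the trapezoidal
integral of C up to an upper limit (default: first zero crossing, capped
at 10 ps).  For well-averaged curves the short- and long-time decay
constants come from a double-exponential fit

    C(t) = a * exp(-t / tau_s) + (1 - a) * exp(-t / tau_l),

with nonnegative amplitudes summing to C(0) = 1, and the effective decay
constant is the amplitude-weighted mean

    tau_eff = a * tau_s + (1 - a) * tau_l.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ACFResult",
    "ACFFit",
    "ACFError",
    "compute_acf",
    "relaxation_time",
    "fit_double_exponential",
]

#: cap on the automatic integration limit for tau_CN, ps
TAU_CN_LIMIT_CAP = 10.0
#: default double-exponential fit window, ps
FIT_WINDOW_DEFAULT = (0.0, 5.0)
#: relative tau separation below which the fit is flagged single-exponential
DEGENERATE_RTOL = 0.05


class ACFError(ValueError):
    """Degenerate input or failed fit in the ACF analysis."""


@dataclass
class ACFResult:
    """Normalized CN autocorrelation on a uniform lag grid."""

    lags: np.ndarray  # ps
    c: np.ndarray  # C(0) = 1
    variance: float  # var(N), dimensionless
    mean: float  # <N>
    dt: float


@dataclass
class ACFFit:
    """Double-exponential decay parameters of a CN autocorrelation."""

    a_s: float
    a_l: float
    tau_s: float  # ps, short decay constant
    tau_l: float  # ps, long decay constant (tau_s <= tau_l)
    tau_eff: float  # ps, amplitude-weighted effective decay constant
    tau_cn: float  # ps, integral relaxation time
    tau_cn_limit: float  # ps, upper integration limit actually used
    degenerate: bool  # tau_s ~ tau_l: effectively single-exponential
    resolved: bool  # False when decay is faster than the sampling interval


def compute_acf(cn: np.ndarray, dt: float, max_lag: float) -> ACFResult:
    """Biased, normalized autocorrelation of a CN series up to ``max_lag`` ps."""
    cn = np.asarray(cn, dtype=float)
    if dt <= 0:
        raise ACFError("dt must be positive")
    n = len(cn)
    if n * dt <= max_lag:
        raise ACFError(f"series ({n * dt:.3g} ps) shorter than max_lag ({max_lag} ps)")
    d = cn - cn.mean()
    var = float(np.dot(d, d) / n)
    if var == 0.0:
        raise ACFError("zero-variance CN series: autocorrelation undefined")
    k_max = int(round(max_lag / dt))
    # biased autocovariance via FFT: c_k = (1/n) sum_t d_t d_{t+k}
    m = 1 << (2 * n - 1).bit_length()
    fd = np.fft.rfft(d, m)
    acov = np.fft.irfft(fd * np.conj(fd), m)[: k_max + 1] / n
    c = acov / acov[0]
    lags = np.arange(k_max + 1) * dt
    return ACFResult(lags=lags, c=c, variance=var, mean=float(cn.mean()), dt=dt)


def relaxation_time(acf: ACFResult, upper_limit: float | None = None) -> tuple[float, float]:
    """Integral relaxation time tau_CN = trapezoid of C(t) from 0 to the limit.

    With ``upper_limit=None`` the limit defaults to the first lag where C
    crosses zero, capped at 10 ps.  Returns ``(tau_cn, limit_used)``.
    """
    if upper_limit is None:
        below = np.nonzero(acf.c <= 0.0)[0]
        limit = float(acf.lags[below[0]]) if len(below) else float(acf.lags[-1])
        limit = min(limit, TAU_CN_LIMIT_CAP, float(acf.lags[-1]))
        if limit <= 0.0:
            limit = float(acf.lags[min(1, len(acf.lags) - 1)])
    else:
        limit = float(upper_limit)
        if limit > acf.lags[-1] + 1e-12:
            raise ACFError(f"integration limit {limit} ps beyond available lags ({acf.lags[-1]} ps)")
    sel = acf.lags <= limit + 1e-12
    tau = float(np.trapezoid(acf.c[sel], acf.lags[sel]))
    return tau, limit


def _double_exp(t: np.ndarray, a: float, tau1: float, tau2: float) -> np.ndarray:
    return a * np.exp(-t / tau1) + (1.0 - a) * np.exp(-t / tau2)


def fit_double_exponential(
    acf: ACFResult,
    fit_window: tuple[float, float] = FIT_WINDOW_DEFAULT,
) -> ACFFit:
    """Least-squares double-exponential fit of C(t) over ``fit_window``.

    Amplitudes are constrained nonnegative and sum to C(0) = 1.  A fit
    with nearly equal decay constants is flagged ``degenerate``; decay
    constants below the sampling interval are flagged unresolved.
    Raises :class:`ACFError` on non-convergence.
    """
    lo, hi = fit_window
    hi = min(hi, float(acf.lags[-1]))
    sel = (acf.lags >= lo) & (acf.lags <= hi)
    t, y = acf.lags[sel], acf.c[sel]
    if len(t) < 4:
        raise ACFError("fit window contains too few lags")

    # initial guess from the empirical e-folding time
    below = np.nonzero(y <= math.exp(-1.0))[0]
    tau0 = float(t[below[0]]) if len(below) and t[below[0]] > 0 else max(0.25 * hi, acf.dt)
    eps = 1e-6 * acf.dt

    def resid(p):
        return _double_exp(t, *p) - y

    best = None
    for a0, f1, f2 in ((0.5, 0.5, 2.0), (0.7, 0.3, 3.0), (0.3, 1.0, 5.0)):
        try:
            sol = least_squares(
                resid, x0=[a0, max(f1 * tau0, eps), max(f2 * tau0, eps)],
                bounds=([0.0, eps, eps], [1.0, np.inf, np.inf]), max_nfev=5000,
            )
        except Exception:  # pragma: no cover - scipy internal failure
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise ACFError("double-exponential fit did not converge")

    a, tau1, tau2 = best.x
    if tau1 <= tau2:
        a_s, tau_s, a_l, tau_l = a, tau1, 1.0 - a, tau2
    else:
        a_s, tau_s, a_l, tau_l = 1.0 - a, tau2, a, tau1
    tau_eff = a_s * tau_s + a_l * tau_l
    tau_cn, limit = relaxation_time(acf)
    degenerate = (tau_l - tau_s) <= DEGENERATE_RTOL * tau_l or min(a_s, a_l) < 1e-3
    resolved = tau_s >= acf.dt or a_s < 1e-3
    return ACFFit(a_s=a_s, a_l=a_l, tau_s=tau_s, tau_l=tau_l, tau_eff=tau_eff,
                  tau_cn=tau_cn, tau_cn_limit=limit, degenerate=degenerate,
                  resolved=resolved)
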