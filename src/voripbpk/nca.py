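"""Non-compartmental PK metrics and model-verification statistics.

AUC uses the linear-up/log-down trapezoid; extrapolation to infinity uses a
terminal log-linear regression (default: last three positive points).
Verification statistics mirror standard PBPK practice: predicted/observed
ratio per study, fold deviation max(r, 1/r), the fraction of ratios inside a
fold range (0.5-2.0 acceptable, 0.8-1.25 stringent; bounds inclusive), and
the coverage of observed points by the simulated 5th-95th percentile band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class PKParameters:
    """Per-subject (or per-study) PK summary; units mg.h/L and mg/L."""

    auc_obs: float | None = None
    auc_inf: float | None = None
    auc_tau: float | None = None
    auc_24h: float | None = None
    cmax: float | None = None
    cl_per_kg: float | None = None   # L/h/kg


def _interp_conc(times: np.ndarray, concs: np.ndarray, t: float) -> float:
    return float(np.interp(t, times, concs))


def auc_trapezoid(times: Sequence[float], concs: Sequence[float],
                  t0: float | None = None, t1: float | None = None) -> float:
    """Linear-up/log-down trapezoidal AUC over [t0, t1] (mg.h/L)."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    t0 = t[0] if t0 is None else float(t0)
    t1 = t[-1] if t1 is None else float(t1)
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9 or t1 < t0:
        raise ValueError(f"window [{t0}, {t1}] outside grid [{t[0]}, {t[-1]}]")
    mask = (t > t0) & (t < t1)
    tt = np.concatenate([[t0], t[mask], [t1]])
    cc = np.concatenate([[_interp_conc(t, c, t0)], c[mask],
                         [_interp_conc(t, c, t1)]])
    total = 0.0
    for (ta, tb), (ca, cb) in zip(zip(tt[:-1], tt[1:]), zip(cc[:-1], cc[1:])):
        dt = tb - ta
        if dt == 0.0:
            continue
        if cb < ca and cb > 0.0 and ca > 0.0:
            total += dt * (ca - cb) / np.log(ca / cb)
        else:
            total += dt * 0.5 * (ca + cb)
    return total


def lambda_z(times: Sequence[float], concs: Sequence[float],
             n_points: int = 3,
             window: tuple[float, float] | None = None) -> float:
    """Terminal slope (1/h) by log-linear regression.

    By default the last `n_points` samples are used; a `window` (t0, t1)
    selects the terminal phase explicitly instead (useful for dense
    simulated grids).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, ct = t[m], c[m]
    else:
        if n_points < 2:
            raise ValueError("need at least 2 points for the terminal slope")
        t, ct = t[-n_points:], c[-n_points:]
    if len(ct) < 2:
        raise ValueError("fewer than 2 points in the terminal phase")
    if np.any(ct <= 0):
        raise ValueError("non-positive concentrations in the terminal phase")
    slope = np.polyfit(t, np.log(ct), 1)[0]
    if slope >= 0:
        raise ValueError("terminal phase is not declining; cannot extrapolate")
    return -slope


def auc_inf(times: Sequence[float], concs: Sequence[float],
            n_points: int = 3,
            window: tuple[float, float] | None = None) -> float:
    """AUC extrapolated to infinity: AUC(0-t_last) + C_last / lambda_z."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    lz = lambda_z(t, c, n_points, window)
    if window is not None:
        t_last = window[1]
        c_last = float(np.interp(t_last, t, c))
        return auc_trapezoid(t, c, t[0], t_last) + c_last / lz
    return auc_trapezoid(t, c) + float(c[-1]) / lz


def pk_summary(result, dose_mg: float | None = None,
               t_last: float | None = None,
               tau_window: tuple[float, float] | None = None,
               window_24h: tuple[float, float] | None = None,
               cmax_window: tuple[float, float] | None = None,
               extrapolate: bool = True, lambda_z_points: int = 3,
               lambda_z_window: tuple[float, float] | None = None) -> PKParameters:
    """PK parameters of one simulated subject.

    `result` is a SimulationResult (or any object with t and conc_mg_l).
    Windows are in hours; auc_inf / cl_per_kg are computed only for
    `extrapolate=True` (single-dose use).
    """
    t, c = np.asarray(result.t), np.asarray(result.conc_mg_l)
    out = PKParameters()
    t_last = t[-1] if t_last is None else t_last
    if t_last > t[-1] + 1e-9:
        raise ValueError("requested t_last beyond simulated time")
    out.auc_obs = auc_trapezoid(t, c, 0.0, t_last)
    if extrapolate:
        out.auc_inf = auc_inf(t, c, lambda_z_points, lambda_z_window)
        if dose_mg is None and getattr(result, "dose_total_mg", None) is not None:
            dose_mg = result.dose_total_mg
        if dose_mg is not None and getattr(result, "body_weight", None):
            out.cl_per_kg = dose_mg / out.auc_inf / result.body_weight
    if tau_window is not None:
        out.auc_tau = auc_trapezoid(t, c, *tau_window)
    if window_24h is not None:
        out.auc_24h = auc_trapezoid(t, c, *window_24h)
    lo, hi = cmax_window if cmax_window is not None else (t[0], t_last)
    m = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not m.any():
        raise ValueError("empty Cmax window")
    out.cmax = float(np.max(c[m]))
    return out


def fold_error(predicted: float, observed: float) -> tuple[float, float]:
    """(predicted/observed ratio, fold deviation max(r, 1/r))."""
    if observed <= 0:
        raise ValueError("observed value must be > 0")
    r = predicted / observed
    return r, max(r, 1.0 / r)


def mean_fold_error(ratios: Sequence[float]) -> float:
    """Geometric mean of predicted/observed ratios."""
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("no ratios given")
    return float(np.exp(np.mean(np.log(r))))


def fold_range_fraction(ratios: Sequence[float], low: float, high: float,
                        inclusive: bool = True) -> int:
    """Percentage of ratios inside [low, high], rounded half-up to integer."""
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("no ratios given")
    if inclusive:
        inside = (r >= low) & (r <= high)
    else:
        inside = (r > low) & (r < high)
    pct = 100.0 * inside.sum() / r.size
    return int(np.floor(pct + 0.5))


def prediction_interval_coverage(results: Sequence, obs_times: Sequence[float],
                                 obs_concs: Sequence[float],
                                 lo_pct: float = 5.0, hi_pct: float = 95.0) -> float:
    """Fraction of observed points inside the simulated percentile band."""
    if len(results) < 20:
        raise ValueError("need >= 20 simulated subjects for a stable band")
    obs_t = np.asarray(obs_times, dtype=float)
    obs_c = np.asarray(obs_concs, dtype=float)
    mat = np.vstack([np.interp(obs_t, r.t, r.conc_mg_l) for r in results])
    lo = np.percentile(mat, lo_pct, axis=0)
    hi = np.percentile(mat, hi_pct, axis=0)
    inside = (obs_c >= lo) & (obs_c <= hi)
    return float(inside.mean())
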