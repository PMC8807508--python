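"""Non-compartmental analysis and trimester-vs-baseline comparisons.

AUC uses the linear-up/log-down trapezoid.  The terminal slope for
single-dose extrapolation to infinity is fitted by log-linear regression
on the last three sampled points, extended backwards while the regression
r² improves — the standard automatic terminal-phase selection.  Apparent
clearance is CL/F = dose / AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = ["PKMetrics", "nca", "steady_state_metrics", "relative_change",
           "accumulation_ratio"]


@dataclass(frozen=True)
class PKMetrics:
    """Model-free PK summary of one concentration-time profile."""

    cmax: float                # ng/mL
    tmax: float                # h
    auc: float                 # ng*h/mL (AUC_0-inf or AUC_tau-ss)
    t_half: float              # h
    cl_over_f: float           # L/h
    c_trough: float | None = None   # ng/mL, steady state only
    mode: str = "single"

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "mode" and getattr(self, f.name) is not None}


class TerminalSlopeError(ValueError):
    pass


def _auc_lin_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    lin = (c1 + c2) / 2.0 * dt
    with np.errstate(divide="ignore", invalid="ignore"):
        log = (c1 - c2) / np.log(c1 / c2) * dt
    down = (c2 < c1) & (c2 > 0) & (c1 > 0)
    seg = np.where(down, log, lin)
    return float(np.sum(seg))


def _terminal_slope(t: np.ndarray, c: np.ndarray,
                    min_points: int = 3) -> tuple[float, float]:
    """(lambda_z 1/h, r^2), last-points log-linear fit extended while
    r^2 improves."""
    pos = c > 0
    t, c = t[pos], c[pos]
    if len(t) < min_points:
        raise TerminalSlopeError("too few positive concentrations for a "
                                 "terminal slope")
    logc = np.log(c)

    def fit(npts: int) -> tuple[float, float]:
        tt, yy = t[-npts:], logc[-npts:]
        slope, intercept = np.polyfit(tt, yy, 1)
        resid = yy - (slope * tt + intercept)
        ss_tot = np.sum((yy - yy.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
        return slope, r2

    best_n = min_points
    slope, best_r2 = fit(best_n)
    n = min_points + 1
    while n <= len(t):
        s, r2 = fit(n)
        if r2 > best_r2:
            slope, best_r2, best_n = s, r2, n
            n += 1
        else:
            break
    if slope >= 0:
        raise TerminalSlopeError(
            f"non-decaying tail (lambda_z = {-slope:.3g}/h <= 0); "
            f"fitted on last {best_n} points")
    return -slope, best_r2


def nca(times, concentrations, dose: float, mode: str = "single") -> PKMetrics:
    """Non-compartmental metrics for a single-dose profile.

    ``dose`` in mg, concentrations in ng/mL, times in h.  ``single`` mode
    extrapolates the AUC tail from the terminal slope; for a steady-state
    interval use :func:`steady_state_metrics`.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if len(t) < 5:
        raise ValueError("at least 5 sampling points are required")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if mode != "single":
        raise ValueError("nca() handles single-dose profiles; use "
                         "steady_state_metrics() for steady state")

    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_t = _auc_lin_up_log_down(t, c)
    lam, _ = _terminal_slope(t, c)
    auc = auc_t + float(c[-1]) / lam
    t_half = math.log(2.0) / lam
    cl_f = dose * 1000.0 / auc   # mg -> ug; ug / (ug*h/L) = L/h
    return PKMetrics(cmax=cmax, tmax=tmax, auc=auc, t_half=t_half,
                     cl_over_f=cl_f, mode="single")


def steady_state_metrics(sim, dose: float,
                         interval: tuple[float, float] | None = None
                         ) -> PKMetrics:
    """NCA over the steady-state interval of a simulation.

    AUC_tau, Cmax-ss, tmax (relative to the interval start) and the trough
    (end-of-interval concentration) come from the marked interval (or an
    explicit ``interval`` override); the terminal half-life is estimated
    from the washout tail.
    """
    if interval is None:
        interval = sim.steady_state_interval
    if interval is None:
        raise ValueError("simulation has no flagged steady-state interval")
    t0, t1 = interval
    t, c = sim.interval_slice(t0, t1)
    auc = _auc_lin_up_log_down(t, c)
    i_max = int(np.argmax(c))
    tail_mask = sim.time >= t1 + 24.0   # skip the first post-interval day
    lam, _ = _terminal_slope(sim.time[tail_mask],
                             sim.plasma_concentration[tail_mask])
    return PKMetrics(
        cmax=float(c[i_max]), tmax=float(t[i_max] - t0), auc=auc,
        t_half=math.log(2.0) / lam, cl_over_f=dose * 1000.0 / auc,
        c_trough=float(c[-1]), mode="steady_state",
    )


def relative_change(pregnant: PKMetrics, baseline: PKMetrics
                    ) -> dict[str, float]:
    """Percent change of each metric versus baseline (positive = higher)."""
    if pregnant.mode != baseline.mode:
        raise ValueError("metrics were computed in different modes")
    out = {}
    for name, value in pregnant.as_dict().items():
        ref = getattr(baseline, name)
        if ref is None or name == "tmax":
            continue
        out[name] = 100.0 * (value - ref) / ref
    return out


def accumulation_ratio(t_half: float, interval: float) -> float:
    """First-order accumulation ratio 1 / (1 - 2^(-tau/t_half))."""
    return 1.0 / (1.0 - 2.0 ** (-interval / t_half))
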