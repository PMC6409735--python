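"""Non-compartmental analysis: trapezoidal AUC, terminal half-life, ratios.

Linear (not log) trapezoids throughout: the sparse four-point destructive
designs these summaries serve make the log-trapezoid unstable near zeros.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .units import UnitError


def _as_curve(times, values):
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size or t.size < 2:
        raise UnitError("curve needs >= 2 matching (time, value) points")
    if np.any(np.diff(t) <= 0):
        raise UnitError("curve times must be strictly increasing")
    return t, y


def auc_trapezoid(times, values, t_start: float, t_end: float) -> float:
    """Linear-trapezoid AUC on [t_start, t_end].

    The window must lie within the curve support; endpoints inside a
    sampling interval are linearly interpolated.
    """
    t, y = _as_curve(times, values)
    if t_start < t[0] or t_end > t[-1] or t_start >= t_end:
        raise UnitError(
            f"window [{t_start}, {t_end}] outside curve support [{t[0]}, {t[-1]}]")
    inner = (t > t_start) & (t < t_end)
    tt = np.concatenate([[t_start], t[inner], [t_end]])
    yy = np.concatenate([[np.interp(t_start, t, y)], y[inner],
                         [np.interp(t_end, t, y)]])
    return float(np.trapezoid(yy, tt))


def terminal_half_life(times, values, n_points: int = 3) -> float:
    """ln 2 over the log-linear slope of the last ``n_points`` samples.

    A growing terminal phase yields a negative half-life, which is
    returned as-is so callers can flag it.
    """
    t, y = _as_curve(times, values)
    if n_points < 2 or n_points > t.size:
        raise UnitError(f"need 2..{t.size} terminal points, got {n_points}")
    tt, yy = t[-n_points:], y[-n_points:]
    if np.any(yy <= 0):
        raise UnitError("terminal half-life needs positive concentrations")
    slope = stats.linregress(tt, np.log(yy)).slope
    if slope == 0:
        raise UnitError("flat terminal phase: half-life undefined")
    return float(-np.log(2.0) / slope)


def exposure_ratio(curve_a, curve_b, window: tuple[float, float]) -> float:
    """AUC ratio of two curves over a shared window.

    Each curve is a ``(times, values)`` pair; the denominator must have a
    positive AUC.
    """
    t0, t1 = window
    auc_a = auc_trapezoid(*curve_a, t0, t1)
    auc_b = auc_trapezoid(*curve_b, t0, t1)
    if auc_b == 0:
        raise UnitError("denominator AUC is zero")
    return auc_a / auc_b
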