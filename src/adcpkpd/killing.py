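"""Occupancy-driven kill and the four-compartment cell-distribution model.

Tubulin occupancy feeds a steep Hill function (the published steepness,
~15, makes the kill essentially a switch near the half-maximal occupancy).
Lethally hit volume leaves the growing compartment and transits three
non-growing compartments, each with mean residence time ``tau``, before
the cells die and (in the coupled PD mode) spill their contents back into
the tumor extracellular space.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import PDParams
from .units import UnitError


def growth_rate(DT: float) -> float:
    """Exponential tumor growth rate, 1/day (0.693/DT)."""
    if DT <= 0:
        raise UnitError(f"doubling time must be > 0 days, got {DT}")
    return 0.693 / DT


def kill_rate(occ_pct: float, Kmax: float, KC50: float, gamma: float) -> float:
    """First-order kill rate (1/day) at tubulin occupancy ``occ_pct`` (%)."""
    if occ_pct <= 0.0:
        return 0.0
    ratio = (occ_pct / KC50) ** gamma
    return Kmax * ratio / (1.0 + ratio)


def tgi_rhs(tv_state, occ_pct: float, pd: PDParams, tau: float | None = None,
            Kmax: float | None = None):
    """Derivatives of the four volume compartments (mm^3/day).

    ``tau``/``Kmax`` overrides support subject-level variability draws.
    """
    tv1, tv2, tv3, tv4 = tv_state
    tau = pd.tau if tau is None else tau
    kmax = pd.Kmax if Kmax is None else Kmax
    kg = growth_rate(pd.DT)
    kill = kill_rate(occ_pct, kmax, pd.KC50, pd.gamma)
    d1 = (kg - kill) * tv1
    d2 = kill * tv1 - tv2 / tau
    d3 = (tv2 - tv3) / tau
    d4 = (tv3 - tv4) / tau
    return d1, d2, d3, d4


def time_to_volume(times, volumes, threshold_mm3: float) -> float:
    """First time the total volume exceeds ``threshold_mm3``.

    Linear interpolation between grid points; ``math.inf`` if the curve
    never crosses.  A curve starting above the threshold returns the first
    grid time.
    """
    times = np.asarray(times, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if times.size == 0 or times.size != volumes.size:
        raise UnitError("curve must be non-empty with matching time grid")
    if volumes[0] > threshold_mm3:
        return float(times[0])
    above = np.nonzero(volumes > threshold_mm3)[0]
    if above.size == 0:
        return math.inf
    i = above[0]
    t0, t1 = times[i - 1], times[i]
    v0, v1 = volumes[i - 1], volumes[i]
    return float(t0 + (threshold_mm3 - v0) * (t1 - t0) / (v1 - v0))
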