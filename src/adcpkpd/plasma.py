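"""Plasma disposition of the conjugate and the free payload.

Two-compartment models for both species.  The conjugate (amounts, nmol)
clears linearly from the central compartment and additionally loses drug by
non-specific deconjugation (``Kdec_P``), which also drives the first-order
decline of the average DAR.  Both the catabolic and the deconjugation route
re-inject free payload into the payload central compartment (nM).
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import PlasmaParams


def plasma_rhs(state, p: PlasmaParams, body_weight: float,
               tumor_flux_ADC: float = 0.0, tumor_flux_Drug: float = 0.0):
    """Time derivative of the plasma state.

    ``state`` is ``(X1_ADC, X2_ADC, C1_Drug, C2_Drug, DAR_bar)`` with
    amounts in nmol per animal and concentrations in nM.  ``tumor_flux_ADC``
    (nmol/day) and ``tumor_flux_Drug`` (nM/day, already scaled to the
    payload central volume) are the losses to the tumor, zero when the
    plasma model runs standalone.
    """
    x1, x2, c1, c2, dar = state
    x1 = max(x1, 0.0)
    x2 = max(x2, 0.0)
    v1a = p.V1_ADC * body_weight
    v2a = p.V2_ADC * body_weight
    v1d = p.V1_Drug * body_weight

    dx1 = (-(p.CL_ADC / p.V1_ADC) * x1
           - (p.CLD_ADC / p.V1_ADC) * x1 + (p.CLD_ADC / p.V2_ADC) * x2
           - p.Kdec_P * x1
           - tumor_flux_ADC)
    dx2 = (p.CLD_ADC / p.V1_ADC) * x1 - (p.CLD_ADC / p.V2_ADC) * x2
    dc1 = (-(p.CL_Drug / p.V1_Drug) * c1
           - (p.CLD_Drug / p.V1_Drug) * c1 + (p.CLD_Drug / p.V1_Drug) * c2
           + p.Kdec_P * x1 * dar / v1d
           + (p.CL_ADC / p.V1_ADC) * x1 * dar / (p.V1_Drug * body_weight)
           - tumor_flux_Drug)
    dc2 = (p.CLD_Drug / p.V2_Drug) * (c1 - c2)
    ddar = -p.Kdec_P * dar
    return dx1, dx2, dc1, dc2, ddar


def dar_profile(DAR0: float, Kdec_P: float, t) -> np.ndarray:
    """Closed-form average DAR: DAR0 * exp(-Kdec_P * t)."""
    return DAR0 * np.exp(-Kdec_P * np.asarray(t, dtype=float))


def two_compartment_closed_form(dose, CL, CLD, V1, V2, extra_loss_rate, t):
    """Analytic central concentration of a two-compartment bolus model.

    First-order loss from central at ``CL/V1 + extra_loss_rate``;
    inter-compartment rates ``CLD/V1`` and ``CLD/V2``.  Returns the central
    concentration ``dose/V1``-scaled (nM if dose in nmol and V1 in L).
    Used as an independent oracle in tests, never by the simulator.
    """
    t = np.asarray(t, dtype=float)
    k10 = CL / V1 + extra_loss_rate
    k12 = CLD / V1
    k21 = CLD / V2
    s = k10 + k12 + k21
    disc = math.sqrt(s * s - 4.0 * k10 * k21)
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    c0 = dose / V1
    if math.isclose(lam1, lam2):
        return c0 * np.exp(-lam1 * t)
    a = c0 * (lam1 - k21) / (lam1 - lam2)
    b = c0 * (k21 - lam2) / (lam1 - lam2)
    return a * np.exp(-lam1 * t) + b * np.exp(-lam2 * t)


def plasma_linear_predict(p: PlasmaParams, dose_nmol: float,
                          body_weight: float, times) -> dict:
    """Analyte predictions from the linear structure of the plasma model.

    With z = X * DAR (conjugated payload amount), the five plasma states
    close into a 6-dim constant-coefficient linear system, solved here by
    eigendecomposition.  This is the fast predictor used by the stage-1
    fit; a test pins it against the ODE engine.
    """
    k10 = p.CL_ADC / p.V1_ADC
    k12 = p.CLD_ADC / p.V1_ADC
    k21 = p.CLD_ADC / p.V2_ADC
    kd10 = p.CL_Drug / p.V1_Drug
    kd12 = p.CLD_Drug / p.V1_Drug
    kd21 = p.CLD_Drug / p.V2_Drug
    kdec = p.Kdec_P
    v1a = p.V1_ADC * body_weight
    v1d = p.V1_Drug * body_weight
    # states: x1, x2, z1 = x1*dar, z2 = x2*dar, c1, c2
    A = np.array([
        [-(k10 + k12 + kdec), k21, 0.0, 0.0, 0.0, 0.0],
        [k12, -k21, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, -(k10 + k12 + 2.0 * kdec), k21, 0.0, 0.0],
        [0.0, 0.0, k12, -(k21 + kdec), 0.0, 0.0],
        [0.0, 0.0, (kdec + k10) / v1d, 0.0, -(kd10 + kd12), kd12],
        [0.0, 0.0, 0.0, 0.0, kd21, -kd21],
    ])
    y0 = np.array([dose_nmol, 0.0, dose_nmol * p.DAR0, 0.0, 0.0, 0.0])
    times = np.asarray(times, dtype=float)
    lam, V = np.linalg.eig(A)
    c = np.linalg.solve(V, y0)
    y = (V @ (c[:, None] * np.exp(lam[:, None] * times[None, :]))).real
    x1, z1, c1 = y[0], y[2], y[4]
    total_tras = x1 / v1a
    conjugated = z1 / v1a
    return {
        "total_trastuzumab": total_tras,
        "conjugated_mmae": conjugated,
        "total_mmae": conjugated + c1,
        "unconjugated_mmae": c1,
    }


def plasma_observables(x1, c1, dar, p: PlasmaParams, body_weight: float) -> dict:
    """Observation equations for the three plasma analytes (nM).

    total trastuzumab = X1/V1; conjugated payload = DAR * X1/V1; total
    payload = conjugated + free; unconjugated payload = C1.
    """
    v1a = p.V1_ADC * body_weight
    total_tras = np.asarray(x1) / v1a
    conjugated = np.asarray(dar) * total_tras
    free = np.asarray(c1)
    return {
        "total_trastuzumab": total_tras,
        "conjugated_mmae": conjugated,
        "total_mmae": conjugated + free,
        "unconjugated_mmae": free,
    }
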