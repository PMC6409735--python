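"""Coupled plasma / tumor / single-cell / TGI simulation.

The full system has 15 states:

====  ==============  =========================  ==============
idx   symbol          meaning                    units
====  ==============  =========================  ==============
0     X1_ADC          central conjugate          nmol
1     X2_ADC          peripheral conjugate       nmol
2     C1_Drug         central free payload       nM
3     C2_Drug         peripheral free payload    nM
4     DAR_bar         average drug/antibody      --
5     ADC_f_ex        tumor extracellular ADC    nM (per total TV)
6     Drug_f_ex       tumor extracellular drug   nmol
7     ADC_b           surface-bound ADC          molecules/cell
8     ADC_lyso        endo/lysosomal ADC         molecules/cell
9     Drug_f          free cytosolic payload     molecules/cell
10    Drug_b          tubulin-bound payload      molecules/cell
11-14 TV1..TV4        volume compartments        mm^3
====  ==============  =========================  ==============

Three modes:

* ``plasma_only`` — the 5 plasma states, tumor decoupled (stage-1 model).
* ``pk_only``     — full system, kill and death-release off; the tumor
  grows exponentially (PK-fitting configuration, default TV0 500 mm^3).
* ``pkpd``        — kill on, dying cells release their contents back into
  the extracellular space (default TV0 375 mm^3).

The right-hand side is a fused scalar implementation for speed; unit tests
assert it agrees with the per-module reference functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import DoseRegimen, ParameterSet
from .plasma import plasma_observables
from .units import MM3_PER_L, UnitError, dose_to_nmol

_FOUR_PI_3 = 4.0 * math.pi / 3.0

PLASMA_STATES = ("X1_ADC", "X2_ADC", "C1_Drug", "C2_Drug", "DAR_bar")
FULL_STATES = PLASMA_STATES + (
    "ADC_f_ex", "Drug_f_ex", "ADC_b", "ADC_lyso", "Drug_f", "Drug_b",
    "TV1", "TV2", "TV3", "TV4")

# typical magnitudes used to scale absolute solver tolerance per state
_STATE_SCALES = np.array([1.0, 1.0, 10.0, 10.0, 4.0,
                          10.0, 0.01, 1e4, 1e4, 1e4, 1e4,
                          500.0, 500.0, 500.0, 500.0])


class SimulationError(RuntimeError):
    """Integrator failure or an unrecoverable negative-state excursion."""


@dataclass
class SimResult:
    """Trajectory plus derived analyte observables."""

    time: np.ndarray
    states: np.ndarray           # (n_states, n_times)
    state_names: tuple
    params: ParameterSet
    regimen: DoseRegimen
    mode: str

    def state(self, name: str) -> np.ndarray:
        return self.states[self.state_names.index(name)]

    @property
    def tv_total(self) -> np.ndarray:
        """Total tumor volume, mm^3 (zeros in plasma_only mode)."""
        if self.mode == "plasma_only":
            return np.zeros_like(self.time)
        return (self.state("TV1") + self.state("TV2")
                + self.state("TV3") + self.state("TV4"))

    def observables(self) -> dict:
        """Analyte map keyed by ``(matrix, analyte)``, concentrations in nM."""
        p = self.params.plasma
        out = {}
        pl = plasma_observables(self.state("X1_ADC"), self.state("C1_Drug"),
                                self.state("DAR_bar"), p,
                                self.regimen.body_weight)
        for analyte, vals in pl.items():
            out[("plasma", analyte)] = vals
        out[("plasma", "dar")] = self.state("DAR_bar")
        if self.mode == "plasma_only":
            return out
        cp = self.params.cell
        tv_mm3 = self.tv_total
        tv_L = tv_mm3 / MM3_PER_L
        n_c = tv_mm3 * cp.cells_per_mm3
        cell_to_nM = n_c * cp.SF / tv_L
        total_tras = self.state("ADC_f_ex") + (
            self.state("ADC_b") + self.state("ADC_lyso")) * cell_to_nM
        unconj = self.state("Drug_f_ex") / tv_L + (
            self.state("Drug_f") + self.state("Drug_b")) * cell_to_nM
        out[("tumor", "total_trastuzumab")] = total_tras
        out[("tumor", "unconjugated_mmae")] = unconj
        out[("tumor", "total_mmae")] = unconj + self.state("DAR_bar") * total_tras
        out[("tumor", "occupancy")] = 100.0 * self.state("Drug_b") / cp.Tub_total_molecules
        out[("tumor", "tumor_volume")] = tv_mm3
        return out

    def observable(self, matrix: str, analyte: str) -> np.ndarray:
        return self.observables()[(matrix, analyte)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_d, matrix, analyte, value, units."""
        rows = []
        units = {"dar": "mol/mol", "occupancy": "%", "tumor_volume": "mm^3"}
        for (matrix, analyte), vals in self.observables().items():
            rows.append(pd.DataFrame({
                "time_d": self.time, "matrix": matrix, "analyte": analyte,
                "value": vals, "units": units.get(analyte, "nM")}))
        return pd.concat(rows, ignore_index=True)


def _plasma_rhs_factory(ps: ParameterSet, bw: float):
    p = ps.plasma
    k10 = p.CL_ADC / p.V1_ADC
    k12 = p.CLD_ADC / p.V1_ADC
    k21 = p.CLD_ADC / p.V2_ADC
    kd10 = p.CL_Drug / p.V1_Drug
    kd12 = p.CLD_Drug / p.V1_Drug
    kd21 = p.CLD_Drug / p.V2_Drug
    kdec = p.Kdec_P
    v1d = p.V1_Drug * bw

    def rhs(t, y):
        x1, x2, c1, c2, dar = y
        if x1 < 0.0:
            x1 = 0.0
        dx1 = -k10 * x1 - k12 * x1 + k21 * x2 - kdec * x1
        dx2 = k12 * x1 - k21 * x2
        dc1 = (-kd10 * c1 - kd12 * c1 + kd12 * c2
               + kdec * x1 * dar / v1d + k10 * x1 * dar / v1d)
        dc2 = kd21 * (c1 - c2)
        ddar = -kdec * dar
        return (dx1, dx2, dc1, dc2, ddar)

    return rhs


def _full_rhs_factory(ps: ParameterSet, bw: float, pkpd: bool,
                      kmax: float | None = None, tau: float | None = None):
    p, td, cp, pdp = ps.plasma, ps.tumor, ps.cell, ps.pd
    k10 = p.CL_ADC / p.V1_ADC
    k12 = p.CLD_ADC / p.V1_ADC
    k21 = p.CLD_ADC / p.V2_ADC
    kd10 = p.CL_Drug / p.V1_Drug
    kd12 = p.CLD_Drug / p.V1_Drug
    kd21 = p.CLD_Drug / p.V2_Drug
    kdec = p.Kdec_P
    v1a = p.V1_ADC * bw
    v1d = p.V1_Drug * bw
    vasc_adc = 2.0 * td.P_ADC * td.R_cap / td.R_Krogh ** 2
    vasc_drug = 2.0 * td.P_Drug * td.R_cap / td.R_Krogh ** 2
    six_d_adc = 6.0 * td.D_ADC
    six_d_drug = 6.0 * td.D_Drug
    eps_a, eps_d = td.eps_ADC, td.eps_Drug
    kon_a, koff_a = cp.Kon_ADC, cp.Koff_ADC
    kint, kdeg = cp.Kint_ADC, cp.Kdeg_ADC
    kon_t = cp.Kon_Tub * cp.SF / cp.V_cell   # per molecule per day
    koff_t = cp.Koff_Tub
    kin, kout = cp.Kin_Drug, cp.Kout_Drug
    ag = cp.Ag_ex
    sf, vcell = cp.SF, cp.V_cell
    dens = cp.cells_per_mm3
    tub_mol = cp.Tub_total_molecules
    kg = 0.693 / pdp.DT
    kmax = pdp.Kmax if kmax is None else kmax
    tau = pdp.tau if tau is None else tau
    kc50, gamma = pdp.KC50, pdp.gamma
    inv_tau = 1.0 / tau

    def rhs(t, y):
        (x1, x2, c1, c2, dar, a_ex, d_ex, a_b, a_ly, d_f, d_b,
         tv1, tv2, tv3, tv4) = y
        if x1 < 0.0:
            x1 = 0.0
        if a_ex < 0.0:
            a_ex = 0.0
        if d_ex < 0.0:
            d_ex = 0.0
        if a_b < 0.0:
            a_b = 0.0
        if d_f < 0.0:
            d_f = 0.0
        if d_b < 0.0:
            d_b = 0.0

        tv_mm3 = tv1 + tv2 + tv3 + tv4
        tv_L = tv_mm3 * 1e-6
        n_c = tv_mm3 * dens
        r2 = (tv_L * 1000.0 / _FOUR_PI_3) ** (2.0 / 3.0)   # cm^2
        ex_adc = vasc_adc + six_d_adc / r2
        ex_drug = vasc_drug + six_d_drug / r2

        grad_adc = x1 / v1a - a_ex / eps_a                  # nM
        flux_adc = grad_adc * tv_L * ex_adc                 # nmol/day
        grad_drug = c1 - d_ex / (tv_L * eps_d)
        flux_drug = grad_drug * tv_L * ex_drug              # nmol/day

        dx1 = -k10 * x1 - k12 * x1 + k21 * x2 - kdec * x1 - flux_adc
        dx2 = k12 * x1 - k21 * x2
        dc1 = (-kd10 * c1 - kd12 * c1 + kd12 * c2
               + kdec * x1 * dar / v1d + k10 * x1 * dar / v1d
               - flux_drug / v1d)
        dc2 = kd21 * (c1 - c2)
        ddar = -kdec * dar

        bind = kon_a * (a_ex / eps_a) * (ag - a_b) - koff_a * a_b
        da_ex = grad_adc * ex_adc - bind * n_c * sf / tv_L - kdec * a_ex
        dd_ex = (flux_drug + kdec * a_ex * dar * tv_L
                 + (kdec * a_b * dar + kout * d_f) * n_c * sf
                 - kin * n_c * (vcell / (tv_L * eps_d)) * d_ex)

        tub_bind = kon_t * d_f * (tub_mol - d_b)
        da_b = bind - (kdec + kint) * a_b - kg * a_b
        da_ly = kint * a_b - kdeg * a_ly - kg * a_ly
        dd_f = (kdeg * a_ly * dar - kout * d_f - tub_bind + koff_t * d_b
                + kin * (vcell / (tv_L * eps_d)) * (d_ex / sf) - kg * d_f)
        dd_b = tub_bind - koff_t * d_b - kg * d_b

        if pkpd:
            occ = 100.0 * d_b / tub_mol
            if occ > 0.0:
                ratio = (occ / kc50) ** gamma
                kill = kmax * ratio / (1.0 + ratio)
            else:
                kill = 0.0
            dtv1 = (kg - kill) * tv1
            dtv2 = kill * tv1 - tv2 * inv_tau
            dtv3 = (tv2 - tv3) * inv_tau
            dtv4 = (tv3 - tv4) * inv_tau
            dying = tv4 * dens * inv_tau
            da_ex += dying * (a_b + a_ly) * sf / tv_L
            dd_ex += dying * (d_f + d_b) * sf
        else:
            dtv1 = kg * tv1
            dtv2 = dtv3 = dtv4 = 0.0

        return (dx1, dx2, dc1, dc2, ddar, da_ex, dd_ex, da_b, da_ly,
                dd_f, dd_b, dtv1, dtv2, dtv3, dtv4)

    return rhs


def simulate(params: ParameterSet, regimen: DoseRegimen | None = None, *,
             t_end: float = 7.0, mode: str = "pk_only",
             tv0: float | None = None, t_eval=None, n_grid: int = 201,
             rtol: float = 1e-8, atol_scale: float = 1e-10,
             kmax: float | None = None, tau: float | None = None) -> SimResult:
    """Integrate the model and return a :class:`SimResult`.

    ``tv0`` defaults to 500 mm^3 in ``pk_only`` mode (PK study design) and
    375 mm^3 in ``pkpd`` mode (TGI study design).  ``kmax``/``tau``
    override the typical PD values for subject-level variability draws.
    Dosing is an instantaneous bolus added to the conjugate central
    compartment at each scheduled time.
    """
    if regimen is None:
        regimen = DoseRegimen()
    if mode not in ("plasma_only", "pk_only", "pkpd"):
        raise UnitError(f"unknown mode '{mode}'")
    bw = regimen.body_weight
    dose_nmol, _ = dose_to_nmol(regimen.dose_mg_per_kg, regimen.MW_ADC, bw)

    if mode == "plasma_only":
        names = PLASMA_STATES
        rhs = _plasma_rhs_factory(params, bw)
        y0 = np.zeros(5)
        y0[4] = params.plasma.DAR0
        scales = _STATE_SCALES[:5]
    else:
        names = FULL_STATES
        rhs = _full_rhs_factory(params, bw, pkpd=(mode == "pkpd"),
                                kmax=kmax, tau=tau)
        y0 = np.zeros(15)
        y0[4] = params.plasma.DAR0
        if tv0 is None:
            tv0 = 500.0 if mode == "pk_only" else params.pd.TV0
        if tv0 <= 0:
            raise UnitError(f"initial tumor volume must be > 0, got {tv0}")
        y0[11] = tv0
        scales = _STATE_SCALES

    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_grid)
    else:
        t_eval = np.asarray(t_eval, dtype=float)
        t_end = max(t_end, float(t_eval[-1]))
    atol = scales * (atol_scale / 1e-10) * 1e-10

    dose_times = [t for t in regimen.times if t <= t_end]
    segments = sorted(set([0.0] + dose_times + [t_end]))
    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    y = y0.copy()
    for left, right in zip(segments[:-1], segments[1:]):
        if left in dose_times:
            y[0] += dose_nmol
        mask = (t_eval >= left) & (t_eval <= right)
        # always give the solver the segment ends so restarts are exact
        seg_eval = np.unique(np.concatenate([[left], t_eval[mask], [right]]))
        sol = solve_ivp(rhs, (left, right), y, method="LSODA",
                        t_eval=seg_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(
                f"integration failed at t={sol.t[-1] if sol.t.size else left}: "
                f"{sol.message}")
        keep = np.isin(sol.t, t_eval[mask])
        times_out.append(sol.t[keep])
        states_out.append(sol.y[:, keep])
        y = sol.y[:, -1].copy()
    if segments[-1] in dose_times:   # dose exactly at t_end: state update only
        y[0] += dose_nmol

    time = np.concatenate(times_out)
    states = np.concatenate(states_out, axis=1)
    # drop duplicated segment-boundary samples
    time, idx = np.unique(time, return_index=True)
    states = states[:, idx]

    # negative-state audit: clip solver undershoot, fail on real excursions
    floor = -1e-4 * scales[:, None]
    if np.any(states < floor):
        worst = states.min(axis=1)
        raise SimulationError(f"negative state excursion beyond band: {worst}")
    np.clip(states, 0.0, None, out=states)

    return SimResult(time=time, states=states, state_names=names,
                     params=params, regimen=regimen, mode=mode)


def total_mmae_nmol(res: SimResult) -> np.ndarray:
    """Total payload amount (nmol) across plasma, tumor and cells.

    Conjugated payload counts as (amount of conjugate) x DAR.  Used by the
    closed-system mass-audit tests.
    """
    p = res.params.plasma
    cp = res.params.cell
    bw = res.regimen.body_weight
    dar = res.state("DAR_bar")
    total = (res.state("X1_ADC") * dar + res.state("X2_ADC") * dar
             + res.state("C1_Drug") * p.V1_Drug * bw
             + res.state("C2_Drug") * p.V2_Drug * bw)
    if res.mode != "plasma_only":
        tv_mm3 = res.tv_total
        tv_L = tv_mm3 / MM3_PER_L
        n_c = tv_mm3 * cp.cells_per_mm3
        total = total + (res.state("ADC_f_ex") * tv_L * dar
                         + res.state("Drug_f_ex")
                         + ((res.state("ADC_b") + res.state("ADC_lyso")) * dar
                            + res.state("Drug_f") + res.state("Drug_b"))
                         * n_c * cp.SF)
    return total
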