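"""Synthetic xenograft study generator.

Emulates the two in-vivo designs the model was built on, so every
calibration stage is testable without external data:

* PK study — single 10 mg/kg IV dose when tumors reach ~500 mm^3; a blood
  sample from every animal at 10 min, then destructive sampling (blood +
  tumor) of three animals per group at 24 h, 72 h and 168 h.  Three
  analytes per matrix: total trastuzumab, total payload, unconjugated
  payload.
* TGI study — dose arms per tumor model (control plus three dose levels,
  n = 7), treatment at ~375 mm^3, tumor volumes measured twice a week up
  to 48 days, administrative censoring once a volume cap is exceeded.

Residual noise is additive on the concentration scale with
SD = sigma_intercept + sigma_slope * Y (the fitted variance model),
truncated at zero.  Subject-level variability on Kmax and tau is
log-normal with the published omegas, applied in simulation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import simulate
from .estimation import PLASMA_ANALYTES, VarianceParams
from .parameters import DoseRegimen, ParameterSet, default_parameters
from .units import UnitError

#: 10 min expressed in days
TEN_MINUTES = 10.0 / (24.0 * 60.0)

#: twice-weekly measurement grid out to the longest reported endpoint
TWICE_WEEKLY_48D = tuple(
    d for w in range(0, 7) for d in (7 * w, 7 * w + 3)) + (48,)


@dataclass(frozen=True)
class PKStudyDesign:
    """Destructive plasma/tumor PK sampling design."""

    models: tuple[str, ...] = ("n87", "mcf7")
    dose_mg_per_kg: float = 10.0
    plasma_times: tuple[float, ...] = (TEN_MINUTES, 1.0, 3.0, 7.0)
    tumor_times: tuple[float, ...] = (1.0, 3.0, 7.0)
    n_per_time: int = 3
    tv0: float = 500.0
    noise: VarianceParams | None = field(
        default_factory=lambda: VarianceParams(0.0, 0.05))
    plasma_tumor_coupled: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_per_time < 1:
            raise UnitError("need at least one animal per time point")


@dataclass(frozen=True)
class TGIStudyDesign:
    """Dose-ranging tumor-growth-inhibition design."""

    arms: tuple = (("mcf7", (0.0, 3.0, 5.0, 10.0)),
                   ("n87", (0.0, 1.0, 3.0, 10.0)))
    n_per_arm: int = 7
    measure_days: tuple[float, ...] = TWICE_WEEKLY_48D
    tv0: float = 375.0
    noise: VarianceParams | None = field(
        default_factory=lambda: VarianceParams(0.0, 0.05))
    omega_Kmax: float = 0.0
    omega_tau: float = 0.0
    volume_cap: float = 2500.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 1:
            raise UnitError("need at least one subject per arm")
        if list(self.measure_days) != sorted(set(self.measure_days)):
            raise UnitError("measurement days must be sorted and unique")


def _noisy(rng, y, noise: VarianceParams | None):
    if noise is None:
        return np.asarray(y, dtype=float)
    sd = noise.sd(y)
    return np.maximum(np.asarray(y) + rng.normal(0.0, 1.0, np.shape(y)) * sd, 0.0)


def generate_pk_dataset(design: PKStudyDesign,
                        params_by_model: dict[str, ParameterSet] | None = None
                        ) -> pd.DataFrame:
    """Long-format PK observation table for the destructive-sampling study.

    Plasma truth comes from the standalone plasma model (the stage-1
    structural model) unless ``plasma_tumor_coupled`` is set; tumor truth
    always comes from the full coupled PK simulation.  Each tumor animal
    contributes one tumor time point (destructive sampling).
    """
    if params_by_model is None:
        params_by_model = {m: default_parameters(m) for m in design.models}
    rng = np.random.default_rng(design.seed)
    reg = DoseRegimen(dose_mg_per_kg=design.dose_mg_per_kg)
    rows = []
    for model in design.models:
        ps = params_by_model[model]
        t_end = max(design.plasma_times[-1], design.tumor_times[-1])
        full = simulate(ps, reg, mode="pk_only", tv0=design.tv0,
                        t_eval=np.unique(np.concatenate(
                            [design.plasma_times, design.tumor_times])),
                        t_end=t_end)
        plasma_src = full if design.plasma_tumor_coupled else simulate(
            ps, reg, mode="plasma_only", t_eval=design.plasma_times,
            t_end=t_end)
        obs_p = plasma_src.observables()
        obs_t = full.observables()
        subj = 0
        for t in design.plasma_times:
            for _ in range(design.n_per_time):
                subj += 1
                for analyte in PLASMA_ANALYTES:
                    y = float(np.interp(t, plasma_src.time,
                                        obs_p[("plasma", analyte)]))
                    rows.append((t, "plasma", analyte, model,
                                 design.dose_mg_per_kg,
                                 f"{model}-p{subj:02d}",
                                 float(_noisy(rng, y, design.noise)), "nM"))
        subj = 0
        for t in design.tumor_times:
            for _ in range(design.n_per_time):
                subj += 1
                for analyte in PLASMA_ANALYTES:
                    y = float(np.interp(t, full.time, obs_t[("tumor", analyte)]))
                    rows.append((t, "tumor", analyte, model,
                                 design.dose_mg_per_kg,
                                 f"{model}-t{subj:02d}",
                                 float(_noisy(rng, y, design.noise)), "nM"))
    return pd.DataFrame(rows, columns=["time_d", "matrix", "analyte", "model",
                                       "dose_mg_kg", "subject", "value",
                                       "units"])


def generate_tgi_dataset(design: TGIStudyDesign,
                         params_by_model: dict[str, ParameterSet] | None = None
                         ) -> pd.DataFrame:
    """Long-format tumor-volume table for the dose-ranging TGI study.

    Per-subject Kmax and tau are drawn log-normally when the omegas are
    positive; control arms carry no kill and hence no PD variability.
    Measurements stop after the first reading above ``volume_cap``.
    """
    if params_by_model is None:
        params_by_model = {m: default_parameters(m) for m, _ in design.arms}
    rng = np.random.default_rng(design.seed)
    days = np.asarray(design.measure_days, dtype=float)
    rows = []
    for model, doses in design.arms:
        ps = params_by_model[model].replace(pd={"TV0": design.tv0})
        for dose in doses:
            reg = DoseRegimen(dose_mg_per_kg=dose)
            typical = None
            for i in range(design.n_per_arm):
                subject = f"{model}-{dose:g}mgkg-{i + 1:02d}"
                vary = dose > 0 and (design.omega_Kmax > 0
                                     or design.omega_tau > 0)
                if vary:
                    kmax_i = ps.pd.Kmax * float(np.exp(rng.normal(0, design.omega_Kmax)))
                    tau_i = ps.pd.tau * float(np.exp(rng.normal(0, design.omega_tau)))
                    res = simulate(ps, reg, mode="pkpd", tv0=design.tv0,
                                   t_eval=days, t_end=float(days[-1]),
                                   kmax=kmax_i, tau=tau_i)
                    curve = np.interp(days, res.time, res.tv_total)
                else:
                    if typical is None:
                        res = simulate(ps, reg, mode="pkpd", tv0=design.tv0,
                                       t_eval=days, t_end=float(days[-1]))
                        typical = np.interp(days, res.time, res.tv_total)
                    curve = typical
                noisy = _noisy(rng, curve, design.noise)
                for t, v in zip(days, noisy):
                    rows.append((t, "tumor", "tumor_volume", model, dose,
                                 subject, float(v), "mm^3"))
                    if v > design.volume_cap:
                        break
    return pd.DataFrame(rows, columns=["time_d", "matrix", "analyte", "model",
                                       "dose_mg_kg", "subject", "value",
                                       "units"])
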