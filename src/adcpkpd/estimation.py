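"""Maximum-likelihood fitting with a combined-error variance model.

The observation variance follows ``Var(t) = (sigma_intercept +
sigma_slope * Y(t))^2`` evaluated at the model prediction ``Y``.  The
objective is minus twice the Gaussian log-likelihood (constant dropped):

    -2LL = sum_i [ (y_i - Y_i)^2 / Var_i + ln Var_i ]

Sigma pairs are per analyte/matrix stream.  When a stream's sigmas are not
fixed, ``sigma_slope`` is profiled analytically with ``sigma_intercept``
held at a configured value (default 0): for a purely proportional error
the profiled optimum is ``sigma_slope^2 = mean(((y-Y)/Y)^2)`` and the
concentrated objective is ``n (1 + ln s^2) + 2 sum ln Y``.

Calibration is sequential, mirroring the staged model development:

* stage ``plasma`` — frees {CL_ADC, CLD_ADC, V1_ADC, V2_ADC, Kdec_P}
  against the three plasma analytes (standalone plasma model);
* stage ``tumor``  — freezes plasma, frees the per-cell antigen count
  ``Ag_ex`` (one per tumor model) against the tumor analytes;
* stage ``pd``     — freezes PK, frees {Kmax, KC50, tau} (optionally
  gamma, DT) against the tumor-volume curves of all dose arms.

Fixed-effect pooled ML only; subject-level variability is supported by the
simulator, not estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .engine import SimulationError, simulate
from .plasma import plasma_linear_predict
from .units import dose_to_nmol
from .parameters import DoseRegimen, ParameterSet
from .units import UnitError

_PRED_FLOOR = 1e-9
_PENALTY = 1e12

PLASMA_ANALYTES = ("total_trastuzumab", "total_mmae", "unconjugated_mmae")


@dataclass(frozen=True)
class VarianceParams:
    """Residual-error model: SD(Y) = sigma_intercept + sigma_slope * Y."""

    sigma_intercept: float = 0.0
    sigma_slope: float = 0.05

    def __post_init__(self):
        if self.sigma_intercept < 0 or self.sigma_slope < 0:
            raise UnitError("sigma components must be >= 0")
        if self.sigma_intercept == 0 and self.sigma_slope == 0:
            raise UnitError("at least one sigma component must be positive")

    def sd(self, y):
        return self.sigma_intercept + self.sigma_slope * np.asarray(y)


@dataclass
class FitResult:
    """Estimates with precision and convergence metadata for one stage."""

    stage: str
    estimates: dict
    cv_pct: dict | None
    objective: float
    converged: bool
    n_obs: int
    n_evals: int = 0
    message: str = ""


def neg2_loglik(y, y_pred, var: VarianceParams | None = None,
                sigma_intercept: float = 0.0) -> float:
    """-2 log-likelihood for one stream.

    With ``var`` given, both sigmas are fixed; otherwise ``sigma_slope``
    is profiled analytically at the given intercept (which must then be 0
    for the closed form to apply; a nonzero intercept falls back to a
    1-D numerical profile).
    """
    y = np.asarray(y, dtype=float)
    yp = np.maximum(np.asarray(y_pred, dtype=float), _PRED_FLOOR)
    if var is not None:
        sd = np.maximum(var.sd(yp), _PRED_FLOOR)
        return float(np.sum(((y - yp) / sd) ** 2 + 2.0 * np.log(sd)))
    resid = (y - yp) / yp
    if sigma_intercept == 0.0:
        s2 = max(float(np.mean(resid ** 2)), 1e-30)
        return float(y.size * (1.0 + math.log(s2)) + 2.0 * np.sum(np.log(yp)))

    def prof(log_s):
        v = VarianceParams(sigma_intercept, math.exp(log_s))
        return neg2_loglik(y, yp, v)

    res = optimize.minimize_scalar(prof, bounds=(-12, 3), method="bounded")
    return float(res.fun)


def ml_objective(data: pd.DataFrame, pred: pd.Series | np.ndarray,
                 var_by_stream: dict | None = None) -> float:
    """Sum stream-wise -2LL over the (matrix, analyte) groups of ``data``.

    ``pred`` must align with ``data`` row-for-row.
    """
    df = data.assign(_pred=np.asarray(pred, dtype=float))
    total = 0.0
    for key, g in df.groupby(["matrix", "analyte"], sort=False):
        var = None if var_by_stream is None else var_by_stream.get(tuple(key))
        total += neg2_loglik(g["value"].to_numpy(), g["_pred"].to_numpy(), var)
    return total


class _StreamLik:
    """Precomputed stream grouping for fast repeated -2LL evaluation.

    Groups rows by (matrix, analyte) once; each call takes the aligned
    prediction vector and sums the stream-wise profiled (or fixed-sigma)
    -2 log-likelihoods without per-call pandas overhead.
    """

    def __init__(self, data: pd.DataFrame, var_by_stream: dict | None = None):
        self.y = data["value"].to_numpy(dtype=float)
        self.groups = []
        for key, g in data.groupby(["matrix", "analyte"], sort=False):
            var = None if var_by_stream is None else var_by_stream.get(tuple(key))
            self.groups.append((g.index.to_numpy(), var))

    def __call__(self, pred) -> float:
        pred = np.asarray(pred, dtype=float)
        total = 0.0
        for idx, var in self.groups:
            yp = np.maximum(pred[idx], _PRED_FLOOR)
            yv = self.y[idx]
            if var is not None:
                sd = np.maximum(var.sd(yp), _PRED_FLOOR)
                total += float(np.sum(((yv - yp) / sd) ** 2 + 2.0 * np.log(sd)))
            else:
                s2 = max(float(np.mean(((yv - yp) / yp) ** 2)), 1e-30)
                total += float(yv.size * (1.0 + math.log(s2))
                               + 2.0 * np.sum(np.log(yp)))
        return total


def _cv_from_hessian(fun, x_opt, names, step=1e-3):
    """CV% from a finite-difference Hessian of -2LL on log-parameters.

    The covariance of the log-estimates is 2 H^-1; the sd of a log-normal
    log is reported as CV%.  Returns None when the Hessian is not
    positive definite (non-identifiable stage).
    """
    n = len(x_opt)
    h = np.empty((n, n))
    f0 = fun(x_opt)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            h[i, j] = h[j, i] = (
                fun(x_opt + ei + ej) - fun(x_opt + ei - ej)
                - fun(x_opt - ei + ej) + fun(x_opt - ei - ej)) / (4 * step * step)
    try:
        cov = 2.0 * np.linalg.inv(h)
    except np.linalg.LinAlgError:
        return None
    diag = np.diag(cov)
    if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
        return None
    return {name: 100.0 * math.sqrt(v) for name, v in zip(names, diag)}


def _multistart_nm(obj, x0, n_starts, seed, jitter=0.3, **nm_options):
    """Nelder-Mead from the given start plus jittered restarts; best wins."""
    rng = np.random.default_rng(seed)
    best = None
    starts = [np.asarray(x0, dtype=float)]
    starts += [x0 + rng.normal(0.0, jitter, size=len(x0))
               for _ in range(max(0, n_starts - 1))]
    evals = 0
    for s in starts:
        res = optimize.minimize(obj, s, method="Nelder-Mead",
                                options=dict(nm_options))
        evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    best.nfev = evals
    return best


# ---------------------------------------------------------------- plasma

_PLASMA_FREE = ("CL_ADC", "CLD_ADC", "V1_ADC", "V2_ADC", "Kdec_P")
_PLASMA_INIT = {"CL_ADC": 0.05, "CLD_ADC": 0.05, "V1_ADC": 0.1,
                "V2_ADC": 0.1, "Kdec_P": 0.2}


def fit_plasma(data: pd.DataFrame, base: ParameterSet,
               regimen: DoseRegimen | None = None, init: dict | None = None,
               n_starts: int = 5, seed: int = 0,
               var_by_stream: dict | None = None) -> FitResult:
    """Stage "plasma": refit the conjugate disposition + deconjugation rate.

    ``data`` holds plasma-matrix rows of the three analytes (pooled over
    tumor groups); the payload disposition parameters stay fixed.
    """
    if regimen is None:
        regimen = DoseRegimen()
    df = data[data["matrix"] == "plasma"].reset_index(drop=True)
    if df.empty:
        raise UnitError("no plasma observations supplied")
    times = np.unique(df["time_d"].to_numpy())
    init = {**_PLASMA_INIT, **(init or {})}
    x0 = np.log([init[k] for k in _PLASMA_FREE])
    lik = _StreamLik(df, var_by_stream)
    t_idx = np.searchsorted(times, df["time_d"].to_numpy())
    a_idx = np.array([PLASMA_ANALYTES.index(a) for a in df["analyte"]])

    dose_nmol, _ = dose_to_nmol(regimen.dose_mg_per_kg, regimen.MW_ADC,
                                regimen.body_weight)

    def predictions(x):
        vals = dict(zip(_PLASMA_FREE, np.exp(x)))
        ps = base.replace(plasma=vals)
        obs = plasma_linear_predict(ps.plasma, dose_nmol,
                                    regimen.body_weight, times)
        grid = np.vstack([obs[a] for a in PLASMA_ANALYTES])
        return grid[a_idx, t_idx]

    def obj(x):
        if np.any(np.abs(x) > 15):
            return _PENALTY
        try:
            return lik(predictions(x))
        except (SimulationError, UnitError):
            return _PENALTY

    res = _multistart_nm(obj, x0, n_starts, seed,
                         xatol=2e-4, fatol=1e-3, maxfev=800, maxiter=800)
    est = dict(zip(_PLASMA_FREE, np.exp(res.x)))
    cv = _cv_from_hessian(obj, res.x, _PLASMA_FREE)
    return FitResult("plasma", est, cv, float(res.fun), bool(res.success),
                     len(df), res.nfev, res.message)


# ----------------------------------------------------------------- tumor

def fit_tumor(data: pd.DataFrame, base: ParameterSet,
              regimen: DoseRegimen | None = None, tv0: float = 500.0,
              bounds: tuple[float, float] = (1e3, 1e7),
              var_by_stream: dict | None = None) -> FitResult:
    """Stage "tumor": refit the per-cell antigen count ``Ag_ex`` only.

    ``base`` carries the frozen plasma estimates; ``data`` holds the
    tumor-matrix analytes for a single tumor model.
    """
    if regimen is None:
        regimen = DoseRegimen()
    df = data[data["matrix"] == "tumor"].reset_index(drop=True)
    if df.empty:
        raise UnitError("no tumor observations supplied")
    times = np.unique(df["time_d"].to_numpy())
    t_eval = np.unique(np.concatenate([[0.0], times]))
    lik = _StreamLik(df, var_by_stream)
    t_idx = np.searchsorted(t_eval, df["time_d"].to_numpy())
    a_idx = np.array([PLASMA_ANALYTES.index(a) for a in df["analyte"]])

    def predictions(log_ag):
        ps = base.replace(cell={"Ag_ex": math.exp(log_ag)})
        res = simulate(ps, regimen, mode="pk_only", tv0=tv0, t_eval=t_eval,
                       t_end=float(t_eval[-1]), rtol=1e-6, atol_scale=1e-8)
        obs = res.observables()
        grid = np.vstack([obs[("tumor", a)] for a in PLASMA_ANALYTES])
        return grid[a_idx, t_idx]

    def obj(log_ag):
        try:
            return lik(predictions(log_ag))
        except (SimulationError, UnitError):
            return _PENALTY

    res = optimize.minimize_scalar(obj, bounds=(math.log(bounds[0]),
                                                math.log(bounds[1])),
                                   method="bounded",
                                   options={"xatol": 1e-5})
    est = {"Ag_ex": math.exp(res.x)}
    cv = _cv_from_hessian(lambda x: obj(x[0]), np.array([res.x]), ["Ag_ex"])
    return FitResult("tumor", est, cv, float(res.fun), bool(res.success),
                     len(df), res.nfev)


# -------------------------------------------------------------------- pd

_PD_INIT = {"Kmax": 0.5, "KC50": 90.0, "tau": 3.0, "gamma": 10.0}
_PD_BOUNDS = {"Kmax": (0.01, 20.0), "KC50": (10.0, 100.0),
              "tau": (0.1, 30.0), "gamma": (1.0, 30.0)}


def fit_pd(data: pd.DataFrame, params_by_model: dict[str, ParameterSet],
           free: tuple[str, ...] = ("Kmax", "KC50", "tau"),
           init: dict | None = None, seed: int = 0, n_starts: int = 1,
           tv0: float | None = None, sim_rtol: float = 1e-6,
           var_by_stream: dict | None = None) -> FitResult:
    """Stage "pd": refit the kill parameters from tumor-volume curves.

    ``data`` holds ``analyte == 'tumor_volume'`` rows with ``model`` and
    ``dose_mg_kg`` columns; the PD parameters are shared across tumor
    models (per-model DT stays at its frozen value).  Control-arm
    predictions do not depend on the free parameters and are computed
    once.
    """
    df = data[data["analyte"] == "tumor_volume"].reset_index(drop=True)
    if df.empty:
        raise UnitError("no tumor-volume observations supplied")
    init = {**_PD_INIT, **(init or {})}
    x0 = np.log([init[k] for k in free])
    lo = np.log([_PD_BOUNDS[k][0] for k in free])
    hi = np.log([_PD_BOUNDS[k][1] for k in free])

    arms = sorted({(m, d) for m, d in zip(df["model"], df["dose_mg_kg"])})
    lik = _StreamLik(df, var_by_stream)
    days, arm_rows, arm_tidx = {}, {}, {}
    for arm in arms:
        rows = np.nonzero((df["model"] == arm[0]).to_numpy()
                          & (df["dose_mg_kg"] == arm[1]).to_numpy())[0]
        t = df["time_d"].to_numpy()[rows]
        days[arm] = np.unique(t)
        arm_rows[arm] = rows
        arm_tidx[arm] = np.searchsorted(days[arm], t)

    def arm_curve(model, dose, overrides):
        ps = params_by_model[model]
        if overrides:
            ps = ps.replace(pd=overrides)
        reg = DoseRegimen(dose_mg_per_kg=dose)
        t_eval = days[(model, dose)]
        res = simulate(ps, reg, mode="pkpd", tv0=tv0, t_eval=t_eval,
                       t_end=float(t_eval[-1]), rtol=sim_rtol,
                       atol_scale=1e-8)
        return res.tv_total

    control_curves = {arm: arm_curve(*arm, {}) for arm in arms if arm[1] == 0}
    pred_buf = np.empty(len(df))

    def predictions(x):
        overrides = dict(zip(free, np.exp(x)))
        for arm in arms:
            curve = (control_curves[arm] if arm[1] == 0
                     else arm_curve(*arm, overrides))
            pred_buf[arm_rows[arm]] = curve[arm_tidx[arm]]
        return pred_buf

    def obj(x):
        if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
            return _PENALTY + float(np.sum(np.maximum(lo - x, 0) ** 2
                                           + np.maximum(x - hi, 0) ** 2))
        try:
            return lik(predictions(x))
        except (SimulationError, UnitError):
            return _PENALTY

    res = _multistart_nm(obj, x0, n_starts, seed,
                         xatol=1e-3, fatol=3e-3, maxfev=450, maxiter=450)
    est = dict(zip(free, np.exp(res.x)))
    cv = _cv_from_hessian(obj, res.x, list(free), step=5e-3)
    return FitResult("pd", est, cv, float(res.fun), bool(res.success),
                     len(df), res.nfev, res.message)


# ------------------------------------------------------------ sequencing

def fit_stage(stage: str, data: pd.DataFrame, base, **kwargs) -> FitResult:
    """Dispatch one calibration stage by name (plasma | tumor | pd)."""
    if stage == "plasma":
        return fit_plasma(data, base, **kwargs)
    if stage == "tumor":
        return fit_tumor(data, base, **kwargs)
    if stage == "pd":
        return fit_pd(data, base, **kwargs)
    raise UnitError(f"unknown stage '{stage}'")


def sequential_calibration(bundle: dict,
                           params_by_model: dict[str, ParameterSet],
                           seed: int = 0, **pd_kwargs) -> list[FitResult]:
    """Run plasma -> tumor -> pd, freezing upstream estimates.

    ``bundle`` maps 'plasma'/'tumor'/'tgi' to observation tables; missing
    downstream tables skip the remaining stages with a notice in the
    returned results.  Antigen counts are fit per model from the tumor
    table's ``model`` column.
    """
    results: list[FitResult] = []
    if "plasma" not in bundle:
        raise UnitError("sequential calibration requires a plasma table")
    any_model = next(iter(params_by_model))
    stage1 = fit_plasma(bundle["plasma"], params_by_model[any_model], seed=seed)
    results.append(stage1)
    frozen = {m: ps.replace(plasma=stage1.estimates)
              for m, ps in params_by_model.items()}

    if "tumor" not in bundle:
        results.append(FitResult("tumor", {}, None, math.nan, False, 0,
                                 message="skipped: no tumor table"))
        results.append(FitResult("pd", {}, None, math.nan, False, 0,
                                 message="skipped: upstream stage missing"))
        return results
    for model in sorted(frozen):
        sub = bundle["tumor"]
        sub = sub[sub["model"] == model]
        if sub.empty:
            continue
        r = fit_tumor(sub, frozen[model])
        r.stage = f"tumor:{model}"
        results.append(r)
        frozen[model] = frozen[model].replace(cell=r.estimates)

    if "tgi" not in bundle:
        results.append(FitResult("pd", {}, None, math.nan, False, 0,
                                 message="skipped: no TGI table"))
        return results
    results.append(fit_pd(bundle["tgi"], frozen, seed=seed, **pd_kwargs))
    return results
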