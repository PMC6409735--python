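"""Likelihood identities, stage fits on noiseless data, calibration order."""

import numpy as np
import pandas as pd
import pytest

from adcpkpd.datasets import (PKStudyDesign, TGIStudyDesign,
                              generate_pk_dataset, generate_tgi_dataset)
from adcpkpd.estimation import (VarianceParams, fit_plasma, fit_tumor,
                                ml_objective, neg2_loglik,
                                sequential_calibration)
from adcpkpd.units import UnitError


def test_neg2_loglik_identities():
    y = np.array([1.0, 2.0, 3.0])
    var = VarianceParams(1.0, 0.0)   # unit SD everywhere
    # exact fit with Var = 1: residual and log terms both vanish
    assert neg2_loglik(y, y, var) == pytest.approx(0.0, abs=1e-12)
    # one observation off by exactly sigma_intercept: one standardized
    # residual of 1
    assert neg2_loglik(np.array([2.0]), np.array([1.0]), var) == \
        pytest.approx(1.0)


def test_variance_params_validation():
    with pytest.raises(UnitError):
        VarianceParams(0.0, 0.0)
    with pytest.raises(UnitError):
        VarianceParams(-0.1, 0.1)
    assert VarianceParams(0.0, 0.05).sd(100.0) == pytest.approx(5.0)


def test_ml_objective_minimized_at_truth_noiseless(n87):
    """On noiseless plasma data the -2LL (fixed sigma) is minimal at the
    generating parameters over a grid around the truth."""
    design = PKStudyDesign(models=("n87",), noise=None, seed=0)
    data = generate_pk_dataset(design, {"n87": n87})
    df = data[data["matrix"] == "plasma"].reset_index(drop=True)
    var = {("plasma", a): VarianceParams(0.0, 0.05)
           for a in df["analyte"].unique()}

    def objective(kdec_scale):
        ps = n87.replace(plasma={"Kdec_P": 0.323 * kdec_scale})
        from adcpkpd.engine import simulate
        from adcpkpd.parameters import DoseRegimen
        times = np.unique(df["time_d"])
        res = simulate(ps, DoseRegimen(), mode="plasma_only",
                       t_eval=times, t_end=7.0)
        obs = res.observables()
        lut = {a: dict(zip(res.time, obs[("plasma", a)]))
               for a in df["analyte"].unique()}
        pred = [lut[a][t] for a, t in zip(df["analyte"], df["time_d"])]
        return ml_objective(df, np.array(pred), var)

    vals = {s: objective(s) for s in (0.7, 0.9, 1.0, 1.1, 1.4)}
    assert min(vals, key=vals.get) == 1.0


def test_fit_plasma_from_truth_init_converges_immediately(n87):
    design = PKStudyDesign(models=("n87",), noise=None, seed=3)
    data = generate_pk_dataset(design, {"n87": n87})
    truth_init = {"CL_ADC": 0.033, "CLD_ADC": 0.0585, "V1_ADC": 0.084,
                  "V2_ADC": 0.051, "Kdec_P": 0.323}
    fit = fit_plasma(data, n87, init=truth_init, n_starts=1)
    for k, v in truth_init.items():
        assert fit.estimates[k] == pytest.approx(v, rel=1e-2)


def test_fit_plasma_row_order_invariance(n87):
    design = PKStudyDesign(models=("n87",), seed=11)
    data = generate_pk_dataset(design, {"n87": n87})
    shuffled = data.sample(frac=1.0, random_state=5).reset_index(drop=True)
    f1 = fit_plasma(data, n87, n_starts=1, seed=2)
    f2 = fit_plasma(shuffled, n87, n_starts=1, seed=2)
    for k in f1.estimates:
        assert f1.estimates[k] == pytest.approx(f2.estimates[k], rel=1e-6)


def test_multistart_agreement_plasma(n87):
    """Five jittered starts agree on the plasma optimum to <0.5%."""
    design = PKStudyDesign(models=("n87",), seed=21)
    data = generate_pk_dataset(design, {"n87": n87})
    fits = [fit_plasma(data, n87, n_starts=1, seed=s) for s in range(5)]
    for k in fits[0].estimates:
        vals = np.array([f.estimates[k] for f in fits])
        assert np.max(np.abs(vals - vals.mean()) / vals.mean()) < 5e-3


def test_fit_tumor_recovers_antigen_noiseless(n87, mcf7):
    for ps, truth in ((n87, 185_000.0), (mcf7, 22_400.0)):
        design = PKStudyDesign(models=(ps.name,), noise=None, seed=0)
        data = generate_pk_dataset(design, {ps.name: ps})
        fit = fit_tumor(data, ps)
        assert fit.estimates["Ag_ex"] == pytest.approx(truth, rel=2e-2)
        assert fit.cv_pct is not None and fit.cv_pct["Ag_ex"] >= 0


def test_pd_profile_sanity_kc50_far_from_truth_worse(n87, mcf7):
    """Fixing KC50 at 80% measurably worsens the PD objective relative to
    the generating value on synthetic noiseless TGI data."""
    params = {"n87": n87, "mcf7": mcf7}
    design = TGIStudyDesign(seed=0, n_per_arm=1, noise=None)
    data = generate_tgi_dataset(design, params)
    df = data.reset_index(drop=True)
    var = {("tumor", "tumor_volume"): VarianceParams(0.0, 0.05)}

    def objective(kc50):
        from adcpkpd.engine import simulate
        from adcpkpd.parameters import DoseRegimen
        preds = np.empty(len(df))
        for (m, d), g in df.groupby(["model", "dose_mg_kg"]):
            ps = params[m].replace(pd={"KC50": kc50, "TV0": 375.0})
            days = np.unique(g["time_d"])
            res = simulate(ps, DoseRegimen(dose_mg_per_kg=d), mode="pkpd",
                           tv0=375.0, t_eval=days, t_end=float(days[-1]),
                           rtol=1e-6, atol_scale=1e-8)
            lut = dict(zip(res.time, res.tv_total))
            preds[g.index] = [lut[t] for t in g["time_d"]]
        return ml_objective(df, preds, var)

    assert objective(80.0) > objective(96.8) + 100.0


def test_sequential_calibration_partial_bundle(n87, mcf7):
    design = PKStudyDesign(seed=5)
    data = generate_pk_dataset(design, {"n87": n87, "mcf7": mcf7})
    bundle = {"plasma": data[data["matrix"] == "plasma"]}
    results = sequential_calibration(bundle, {"n87": n87, "mcf7": mcf7})
    stages = [r.stage for r in results]
    assert stages[0] == "plasma" and results[0].estimates
    assert any("skipped" in r.message for r in results[1:])


def test_sequential_calibration_requires_plasma(n87):
    with pytest.raises(UnitError):
        sequential_calibration({}, {"n87": n87})


def test_sequential_calibration_end_to_end(n87, mcf7):
    """Full bundle at truth with low noise: all three stages converge and
    the headline parameters land near their generating values."""
    from adcpkpd.estimation import VarianceParams
    params = {"n87": n87, "mcf7": mcf7}
    pk = generate_pk_dataset(PKStudyDesign(seed=17), params)
    tgi = generate_tgi_dataset(TGIStudyDesign(seed=17, n_per_arm=1), params)
    bundle = {"plasma": pk[pk["matrix"] == "plasma"],
              "tumor": pk[pk["matrix"] == "tumor"],
              "tgi": tgi}
    results = sequential_calibration(bundle, params, seed=17)
    by_stage = {r.stage: r for r in results}
    assert by_stage["plasma"].estimates["Kdec_P"] == pytest.approx(
        0.323, rel=0.15)
    assert by_stage["tumor:n87"].estimates["Ag_ex"] == pytest.approx(
        185_000, rel=0.20)
    assert by_stage["tumor:mcf7"].estimates["Ag_ex"] == pytest.approx(
        22_400, rel=0.20)
    pd_fit = by_stage["pd"]
    assert pd_fit.estimates["Kmax"] == pytest.approx(1.03, rel=0.25)
    assert pd_fit.estimates["tau"] == pytest.approx(2.03, rel=0.25)
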