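"""Single-cell disposition: binding equilibria, occupancy, dilution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adcpkpd.cell import cell_equilibrium_bound, cell_rhs, tubulin_occupancy
from adcpkpd.engine import simulate
from adcpkpd.parameters import DoseRegimen


def test_equilibrium_bound_identities(n87):
    cp = n87.cell
    kd = cp.Kd_ADC
    assert cell_equilibrium_bound(kd, 185_000, cp.Kon_ADC, cp.Koff_ADC) == \
        pytest.approx(92_500, rel=1e-12)
    assert cell_equilibrium_bound(1e9, 185_000, cp.Kon_ADC, cp.Koff_ADC) == \
        pytest.approx(185_000, rel=1e-6)   # saturation
    assert cell_equilibrium_bound(0.0, 185_000, cp.Kon_ADC, cp.Koff_ADC) == 0.0


def test_surface_binding_reaches_langmuir_steady_state(n87):
    """Binding alone (internalization/dilution/deconjugation switched off)
    settles at Ag*C/(Kd+C) with Kd = Koff/Kon = 0.4667 nM."""
    ps = n87.replace(cell={"Kint_ADC": 1e-12})
    cp, td = ps.cell, ps.tumor
    assert cp.Kd_ADC == pytest.approx(0.4667, rel=1e-3)
    c_int = 2.0                      # free interstitial nM
    adc_f_ex = c_int * td.eps_ADC    # state is per total tumor volume
    from scipy.integrate import solve_ivp

    def rhs(t, y):
        d = cell_rhs((y[0], 0.0, 0.0, 0.0), adc_f_ex, 0.0, 0.0, 5e-4,
                     cp, td, Kdec_P=0.0, DT=1e12)
        return [d[0]]

    sol = solve_ivp(rhs, (0, 50), [0.0], rtol=1e-10, atol=1e-6)
    expected = cell_equilibrium_bound(c_int, cp.Ag_ex, cp.Kon_ADC,
                                      cp.Koff_ADC)
    assert sol.y[0, -1] == pytest.approx(expected, rel=1e-6)


def test_tubulin_occupancy_values(n87):
    cp = n87.cell
    assert tubulin_occupancy(0.0, cp) == 0.0
    assert tubulin_occupancy(cp.Tub_total_molecules / 2, cp) == 50.0
    assert tubulin_occupancy(37_187.0, cp) == pytest.approx(95.0, rel=1e-3)


def test_occupancy_half_max_at_tubulin_kd(n87):
    """Free cytosolic payload held at Kd_tub (29.78 nM) gives 50% occupancy."""
    cp, td = n87.tumor, None
    cp = n87.cell
    assert cp.Kd_Tub == pytest.approx(29.78, rel=1e-3)
    drug_f = cp.Kd_Tub * 1e-9 * cp.V_cell * 6.02214076e23  # molecules at Kd
    from scipy.integrate import solve_ivp

    def rhs(t, y):
        bind = cp.Kon_Tub * (cp.SF / cp.V_cell) * drug_f * \
            (cp.Tub_total_molecules - y[0])
        return [bind - cp.Koff_Tub * y[0]]

    sol = solve_ivp(rhs, (0, 10), [0.0], rtol=1e-10, atol=1e-6)
    assert tubulin_occupancy(sol.y[0, -1], cp) == pytest.approx(50.0, rel=1e-4)


def test_saturable_retention_is_concave(n87):
    """Doubling the free payload less-than-doubles equilibrium tubulin load
    above half-occupancy (saturable intracellular binding)."""
    cp = n87.cell
    c = cp.Kd_Tub * 1.5
    b1 = cell_equilibrium_bound(c, cp.Tub_total_molecules, cp.Kon_Tub,
                                cp.Koff_Tub)
    b2 = cell_equilibrium_bound(2 * c, cp.Tub_total_molecules, cp.Kon_Tub,
                                cp.Koff_Tub)
    assert b2 < 2 * b1


@given(dose=st.floats(min_value=0.1, max_value=20.0),
       ag=st.floats(min_value=5e3, max_value=1e6))
@settings(max_examples=10, deadline=None)
def test_occupancy_bounded_on_trajectories(dose, ag, n87):
    ps = n87.replace(cell={"Ag_ex": ag})
    res = simulate(ps, DoseRegimen(dose_mg_per_kg=dose), mode="pkpd",
                   t_end=21.0, n_grid=64, rtol=1e-6, atol_scale=1e-8)
    occ = res.observables()[("tumor", "occupancy")]
    assert np.all(occ >= 0.0) and np.all(occ <= 100.0 + 1e-6)


def test_growth_dilution_conserves_total_cell_content(n87):
    """With exchange, degradation and binding transfer switched off, the
    -0.693/DT per-cell dilution exactly offsets the growth of the cell
    count: per-cell content times N_C(t) is constant."""
    ps = n87.replace(cell={"Kint_ADC": 1e-15, "Kdeg_ADC": 1e-15,
                           "Kon_ADC": 1e-15, "Koff_ADC": 1e-15,
                           "Kon_Tub": 1e-15, "Koff_Tub": 1e-15,
                           "Kin_Drug": 1e-15, "Kout_Drug": 1e-15})
    cp, td = ps.cell, ps.tumor
    DT = 5.0
    kg = 0.693 / DT
    from scipy.integrate import solve_ivp

    def rhs(t, y):
        return cell_rhs(y, 0.0, 0.0, 0.0, 5e-4, cp, td, Kdec_P=0.0, DT=DT)

    y0 = [1000.0, 500.0, 2000.0, 300.0]
    sol = solve_ivp(rhs, (0, 10), y0, rtol=1e-10, atol=1e-12,
                    t_eval=np.linspace(0, 10, 11))
    n_c = np.exp(kg * sol.t)   # normalized cell count
    total = sol.y.sum(axis=0) * n_c
    assert np.max(np.abs(total - total[0]) / total[0]) < 1e-8
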