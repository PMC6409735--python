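"""Single-cell disposition of the conjugate and released payload.

One "average cell" represents the tumor: surface binding to antigen,
internalization to the endo/lysosomal space, proteolytic degradation that
releases ``DAR`` payload molecules per conjugate, cytoplasmic payload
exchange with the extracellular space, and saturable binding to
intracellular tubulin.  Every species carries a dilution term at the tumor
growth rate so that total cell-associated mass is conserved while the cell
population expands.
"""

from __future__ import annotations

from .parameters import CellParams, TumorDistParams


def cell_rhs(cell_state, adc_f_ex: float, drug_f_ex: float, dar: float,
             tv_L: float, cp: CellParams, td: TumorDistParams,
             Kdec_P: float, DT: float):
    """Derivatives of ``(ADC_b, ADC_lyso, Drug_f, Drug_b)``, molecules/cell/day.

    ``adc_f_ex`` is the tumor extracellular conjugate concentration (nM per
    total tumor volume), ``drug_f_ex`` the extracellular payload amount
    (nmol), ``tv_L`` total tumor volume in litres.
    """
    adc_b, adc_lyso, drug_f, drug_b = cell_state
    kg = 0.693 / DT
    tub_mol = cp.Tub_total_molecules
    # second-order tubulin binding: free payload expressed as nM via SF/V_cell
    tub_bind = cp.Kon_Tub * (cp.SF / cp.V_cell) * drug_f * (tub_mol - drug_b)

    d_adc_b = (cp.Kon_ADC * (adc_f_ex / td.eps_ADC) * (cp.Ag_ex - adc_b)
               - cp.Koff_ADC * adc_b
               - (Kdec_P + cp.Kint_ADC) * adc_b
               - kg * adc_b)
    d_adc_lyso = cp.Kint_ADC * adc_b - cp.Kdeg_ADC * adc_lyso - kg * adc_lyso
    d_drug_f = (cp.Kdeg_ADC * adc_lyso * dar
                - cp.Kout_Drug * drug_f
                - tub_bind + cp.Koff_Tub * drug_b
                + cp.Kin_Drug * (cp.V_cell / (tv_L * td.eps_Drug)) * (drug_f_ex / cp.SF)
                - kg * drug_f)
    d_drug_b = tub_bind - cp.Koff_Tub * drug_b - kg * drug_b
    return d_adc_b, d_adc_lyso, d_drug_f, d_drug_b


def tubulin_occupancy(drug_b: float, cp: CellParams) -> float:
    """Percent of intracellular tubulin bound by payload, in [0, 100]."""
    return 100.0 * drug_b / cp.Tub_total_molecules


def cell_equilibrium_bound(c_free_nM: float, Ag: float, Kon: float, Koff: float) -> float:
    """Equilibrium bound count for a saturable binding site: Ag*C/(Kd + C)."""
    kd = Koff / Kon
    return Ag * c_free_nM / (kd + c_free_nM)
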