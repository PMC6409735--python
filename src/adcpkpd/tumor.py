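"""Krogh-cylinder exchange and tumor extracellular balances.

The tumor is treated as a well-mixed sphere exchanging with plasma through
two diffusive routes: permeation across the capillary wall (vascular term,
``2 P R_cap / R_Krogh^2``) and diffusion across the tumor surface
(``6 D / R_tumor^2``).  Surface exchange dominates for small tumors and
vascular exchange for large ones, since the surface term decays with the
square of the tumor radius.

State conventions follow the source model: the conjugate in the tumor
extracellular space is a concentration per total tumor volume (nM); the
free payload there is an amount (nmol).  Interstitial (binding-available)
concentrations divide by the respective void-volume fraction.
"""

from __future__ import annotations

from .parameters import CellParams, TumorDistParams
from .units import UnitError


def exchange_rate(P_um_day: float, D_cm2_day: float, R_cap_um: float,
                  R_Krogh_um: float, R_tumor_cm: float) -> float:
    """First-order plasma<->tumor exchange rate, 1/day.

    ``2 P R_cap / R_Krogh^2`` (µm units cancel) plus ``6 D / R_tumor^2``
    (cm units cancel); both reduce to 1/day.
    """
    if R_tumor_cm <= 0:
        raise UnitError(f"tumor radius must be > 0 cm, got {R_tumor_cm}")
    vascular = 2.0 * P_um_day * R_cap_um / R_Krogh_um ** 2
    surface = 6.0 * D_cm2_day / R_tumor_cm ** 2
    return vascular + surface


def tumor_ex_rhs(adc_f_ex: float, drug_f_ex: float, c1_adc_plasma: float,
                 c1_drug_plasma: float, adc_b: float, adc_lyso: float,
                 drug_f: float, drug_b: float, dar: float, tv_L: float,
                 n_cells: float, tv4_mm3: float, td: TumorDistParams,
                 cp: CellParams, Kdec_P: float, tau: float,
                 R_tumor_cm: float, death_release: bool):
    """Extracellular balances; returns derivatives and plasma-coupling fluxes.

    Returns ``(dADC_f_ex [nM/day], dDrug_f_ex [nmol/day],
    flux_ADC_from_plasma [nmol/day], flux_Drug_from_plasma [nmol/day])``.
    The plasma fluxes are the amounts leaving plasma per day (positive into
    the tumor), so the caller can apply the equal-and-opposite terms.

    ``c1_adc_plasma`` is X1/V1 (nM); ``c1_drug_plasma`` is C1 (nM).  When
    ``death_release`` is on, the cells exiting the last transit compartment
    (volume ``tv4_mm3``) release their per-cell content into the
    extracellular space at rate 1/tau.
    """
    ex_adc = exchange_rate(td.P_ADC, td.D_ADC, td.R_cap, td.R_Krogh, R_tumor_cm)
    ex_drug = exchange_rate(td.P_Drug, td.D_Drug, td.R_cap, td.R_Krogh, R_tumor_cm)

    grad_adc = c1_adc_plasma - adc_f_ex / td.eps_ADC          # nM
    flux_adc = grad_adc * tv_L * ex_adc                        # nmol/day
    grad_drug = c1_drug_plasma - drug_f_ex / (tv_L * td.eps_Drug)
    flux_drug = grad_drug * tv_L * ex_drug                     # nmol/day

    # net binding of interstitial conjugate to cell-surface antigen,
    # molecules/cell/day, converted to nM/day over total tumor volume
    bind = (cp.Kon_ADC * (adc_f_ex / td.eps_ADC) * (cp.Ag_ex - adc_b)
            - cp.Koff_ADC * adc_b)
    d_adc = grad_adc * ex_adc - bind * n_cells * cp.SF / tv_L - Kdec_P * adc_f_ex

    d_drug = (flux_drug
              + Kdec_P * adc_f_ex * dar * tv_L
              + (Kdec_P * adc_b * dar + cp.Kout_Drug * drug_f) * n_cells * cp.SF
              - cp.Kin_Drug * n_cells * (cp.V_cell / (tv_L * td.eps_Drug)) * drug_f_ex)

    if death_release:
        dying_cells = tv4_mm3 * cp.cells_per_mm3 / tau         # cells/day
        d_adc += dying_cells * (adc_b + adc_lyso) * cp.SF / tv_L
        d_drug += dying_cells * (drug_f + drug_b) * cp.SF

    return d_adc, d_drug, flux_adc, flux_drug
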