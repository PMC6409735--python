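"""Unit constants and conversions shared across the model.

The model runs on a single internal unit base:

* time        — days
* ADC         — amounts in nmol (plasma, per animal), concentrations in nM
* payload     — concentrations in nM (plasma), amounts in nmol (tumor
                extracellular space), molecules/cell inside cells
* tumor volume — mm^3 for the growth model, L for exchange/dilution terms
* tumor radius — cm (diffusion term), capillary geometry in µm

``SF`` converts molecules to nmol (1e9 / Avogadro); multiplying a per-cell
molecule count by ``SF`` and dividing by tumor volume in L yields nM.
"""

from __future__ import annotations

import math

AVOGADRO = 6.02214076e23
#: nmol per molecule; SF * AVOGADRO * 1e-9 == 1 by construction.
SF = 1e9 / AVOGADRO

#: mm^3 of tumor per litre
MM3_PER_L = 1e6

#: default tumor cell density: 1e8 cells/g at 1 g/mL -> 1e5 cells/mm^3
CELLS_PER_MM3 = 1e5

HOURS_PER_DAY = 24.0


class UnitError(ValueError):
    """Raised when an input violates a physical-unit precondition."""


def per_hour_to_per_day(rate: float) -> float:
    """Convert a first- or second-order rate constant from 1/h to 1/day."""
    return rate * HOURS_PER_DAY


def dose_to_nmol(dose_mg_per_kg: float, mw_g_per_mol: float,
                 body_weight_kg: float = 0.02) -> tuple[float, float]:
    """Convert an IV bolus dose in mg/kg to molar amounts.

    Returns ``(nmol_per_animal, nmol_per_kg)``.  A zero dose is allowed
    (control arms); negative doses and non-positive molecular weights or
    body weights are rejected.
    """
    if dose_mg_per_kg < 0:
        raise UnitError(f"dose must be >= 0 mg/kg, got {dose_mg_per_kg}")
    if mw_g_per_mol <= 0:
        raise UnitError(f"molecular weight must be > 0, got {mw_g_per_mol}")
    if body_weight_kg <= 0:
        raise UnitError(f"body weight must be > 0, got {body_weight_kg}")
    # mg/kg -> g/kg -> mol/kg -> nmol/kg
    nmol_per_kg = dose_mg_per_kg * 1e6 / mw_g_per_mol
    return nmol_per_kg * body_weight_kg, nmol_per_kg


def radius_from_volume(tv_liters: float) -> float:
    """Radius (cm) of a sphere with volume ``tv_liters``.

    R = (3 * TV * 1000 / (4 pi))^(1/3), with TV in L so TV*1000 is cm^3.
    """
    if tv_liters <= 0:
        raise UnitError(f"tumor volume must be > 0 L, got {tv_liters}")
    return (3.0 * tv_liters * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def volume_from_radius(r_cm: float) -> float:
    """Inverse of :func:`radius_from_volume`; returns litres."""
    if r_cm <= 0:
        raise UnitError(f"radius must be > 0 cm, got {r_cm}")
    return 4.0 * math.pi * r_cm ** 3 / 3.0 / 1000.0


def cells_from_volume(tv_mm3: float, cells_per_mm3: float = CELLS_PER_MM3) -> float:
    """Number of tumor cells in ``tv_mm3`` mm^3 of tumor.

    The default density corresponds to ~1e8 cells per gram of tumor at a
    tissue density of 1 g/mL.
    """
    if tv_mm3 < 0:
        raise UnitError(f"tumor volume must be >= 0 mm^3, got {tv_mm3}")
    if cells_per_mm3 <= 0:
        raise UnitError(f"cell density must be > 0, got {cells_per_mm3}")
    return tv_mm3 * cells_per_mm3


def tubulin_molecules_per_cell(tub_tot_nM: float, v_cell_L: float) -> float:
    """Total tubulin molecules in one cell of volume ``v_cell_L``.

    molecules = concentration (nM = nmol/L) * 1e-9 * V_cell * N_A.
    """
    if tub_tot_nM < 0:
        raise UnitError(f"tubulin concentration must be >= 0 nM, got {tub_tot_nM}")
    if v_cell_L <= 0:
        raise UnitError(f"cell volume must be > 0 L, got {v_cell_L}")
    return tub_tot_nM * 1e-9 * v_cell_L * AVOGADRO
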