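"""Parameter containers with explicit units, validation, and YAML I/O.

All cell-level kinetic rates are stored internally in 1/day (or 1/nM/day
for second-order constants).  Published single-cell rates are usually
reported per hour; the YAML loader converts them once, at load time, when
a field is declared with an ``_per_h`` suffix, so the ODE right-hand side
never mixes time bases.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

from .units import (
    AVOGADRO,
    CELLS_PER_MM3,
    SF,
    UnitError,
    per_hour_to_per_day,
    tubulin_molecules_per_cell,
)


def _require_positive(obj, fields: tuple[str, ...]) -> None:
    for name in fields:
        v = getattr(obj, name)
        if not v > 0:
            raise UnitError(f"{type(obj).__name__}.{name} must be > 0, got {v}")


@dataclass(frozen=True)
class PlasmaParams:
    """Two-compartment disposition of the conjugate and the free payload.

    Clearances in L/day/kg, volumes in L/kg; ``Kdec_P`` (1/day) is the
    non-specific deconjugation rate that also drives the DAR decline;
    ``DAR0`` is the average drug-to-antibody ratio of the dosed material.
    """

    CL_ADC: float = 0.033
    CLD_ADC: float = 0.0585
    V1_ADC: float = 0.084
    V2_ADC: float = 0.051
    CL_Drug: float = 18.40
    CLD_Drug: float = 1.84
    V1_Drug: float = 0.136
    V2_Drug: float = 0.523
    Kdec_P: float = 0.323
    DAR0: float = 4.0

    def __post_init__(self):
        _require_positive(self, ("CL_ADC", "CLD_ADC", "V1_ADC", "V2_ADC",
                                 "CL_Drug", "CLD_Drug", "V1_Drug", "V2_Drug",
                                 "Kdec_P"))
        if self.DAR0 < 0:
            raise UnitError(f"DAR0 must be >= 0, got {self.DAR0}")


@dataclass(frozen=True)
class TumorDistParams:
    """Krogh-cylinder exchange geometry and void volumes.

    ``R_cap``/``R_Krogh`` in µm, permeabilities in µm/day, diffusivities in
    cm^2/day, void-volume fractions dimensionless.
    """

    R_cap: float = 8.0
    R_Krogh: float = 75.0
    P_ADC: float = 334.0
    P_Drug: float = 21000.0
    D_ADC: float = 0.022
    D_Drug: float = 0.25
    eps_ADC: float = 0.24
    eps_Drug: float = 0.44

    def __post_init__(self):
        _require_positive(self, ("R_cap", "R_Krogh", "P_ADC", "P_Drug",
                                 "D_ADC", "D_Drug"))
        for name in ("eps_ADC", "eps_Drug"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise UnitError(f"void volume {name} must be in (0, 1], got {v}")
        if self.R_Krogh <= self.R_cap:
            raise UnitError("R_Krogh must exceed R_cap")


@dataclass(frozen=True)
class CellParams:
    """Single-cell disposition rates, stored in 1/day (1/nM/day).

    ``Ag_ex`` is the per-cell surface antigen count, ``Tub_tot_conc`` the
    intracellular tubulin concentration (nM), ``V_cell`` the cell volume in
    L used to convert between molecules/cell and nM.
    """

    Kon_ADC: float = per_hour_to_per_day(0.03)     # 1/nM/day
    Koff_ADC: float = per_hour_to_per_day(0.014)   # 1/day
    Kint_ADC: float = per_hour_to_per_day(0.11)
    Kdeg_ADC: float = per_hour_to_per_day(0.353)
    Kon_Tub: float = per_hour_to_per_day(0.0183)   # 1/nM/day
    Koff_Tub: float = per_hour_to_per_day(0.545)
    Tub_tot_conc: float = 65.0                     # nM
    Kin_Drug: float = per_hour_to_per_day(8.33)
    Kout_Drug: float = per_hour_to_per_day(0.046)
    Ag_ex: float = 185_000.0                       # receptors/cell
    V_cell: float = 1e-12                          # L
    SF: float = SF                                 # nmol/molecule
    cells_per_mm3: float = CELLS_PER_MM3

    def __post_init__(self):
        _require_positive(self, ("Kon_ADC", "Koff_ADC", "Kint_ADC", "Kdeg_ADC",
                                 "Kon_Tub", "Koff_Tub", "Tub_tot_conc",
                                 "Kin_Drug", "Kout_Drug", "Ag_ex", "V_cell",
                                 "SF", "cells_per_mm3"))
        if not math.isclose(self.SF * AVOGADRO * 1e-9, 1.0, rel_tol=1e-12):
            raise UnitError("SF must equal 1e9 / Avogadro (nmol per molecule)")

    @property
    def Kd_ADC(self) -> float:
        """Equilibrium dissociation constant of the conjugate-antigen pair, nM."""
        return self.Koff_ADC / self.Kon_ADC

    @property
    def Kd_Tub(self) -> float:
        """Equilibrium dissociation constant of the payload-tubulin pair, nM."""
        return self.Koff_Tub / self.Kon_Tub

    @property
    def Tub_total_molecules(self) -> float:
        return tubulin_molecules_per_cell(self.Tub_tot_conc, self.V_cell)


@dataclass(frozen=True)
class PDParams:
    """Occupancy-driven kill model and tumor growth.

    ``Kmax`` (1/day) maximum kill rate, ``KC50`` the tubulin occupancy (%)
    giving half-maximal kill, ``gamma`` the Hill steepness, ``tau`` (days)
    the transit time through the non-growing compartments, ``DT`` (days)
    the tumor doubling time, ``TV0`` (mm^3) the initial volume.  The IIV
    omegas are log-normal standard deviations used only in simulation.
    """

    Kmax: float = 1.03
    KC50: float = 96.8
    gamma: float = 15.02
    tau: float = 2.03
    DT: float = 13.5
    TV0: float = 375.0
    omega_Kmax: float = 0.1016
    omega_tau: float = 0.194

    def __post_init__(self):
        _require_positive(self, ("Kmax", "tau", "DT", "TV0", "gamma"))
        if not 0 < self.KC50 <= 100:
            raise UnitError(f"KC50 must be in (0, 100] %, got {self.KC50}")
        if self.omega_Kmax < 0 or self.omega_tau < 0:
            raise UnitError("IIV omegas must be >= 0")


@dataclass(frozen=True)
class DoseRegimen:
    """IV bolus schedule in mg/kg with the molar-conversion constants."""

    dose_mg_per_kg: float = 10.0
    times: tuple[float, ...] = (0.0,)
    MW_ADC: float = 150_000.0   # g/mol; IgG1 plus ~4 vc-MMAE linkers
    body_weight: float = 0.02   # kg

    def __post_init__(self):
        if self.dose_mg_per_kg < 0:
            raise UnitError("dose must be >= 0 mg/kg")
        _require_positive(self, ("MW_ADC", "body_weight"))
        if any(t < 0 for t in self.times):
            raise UnitError("dose times must be non-negative")
        if list(self.times) != sorted(self.times):
            raise UnitError("dose times must be sorted")


@dataclass(frozen=True)
class ParameterSet:
    """Full parameter vector for one tumor model (plasma/tumor/cell/PD blocks)."""

    plasma: PlasmaParams = field(default_factory=PlasmaParams)
    tumor: TumorDistParams = field(default_factory=TumorDistParams)
    cell: CellParams = field(default_factory=CellParams)
    pd: PDParams = field(default_factory=PDParams)
    name: str = "n87"

    def replace(self, **blocks) -> "ParameterSet":
        """Return a copy with whole blocks or individual fields replaced.

        Accepts block names (``plasma=...``) or dotted field updates via
        keyword dicts, e.g. ``ps.replace(cell={'Ag_ex': 2e4})``.
        """
        updates: dict[str, Any] = {}
        for key, value in blocks.items():
            if isinstance(value, dict):
                current = getattr(self, key)
                updates[key] = dataclasses.replace(current, **value)
            else:
                updates[key] = value
        return dataclasses.replace(self, **updates)


# conversion applied by the YAML loader for fields published per hour
_PER_HOUR_FIELDS = {"Kon_ADC", "Koff_ADC", "Kint_ADC", "Kdeg_ADC",
                    "Kon_Tub", "Koff_Tub", "Kin_Drug", "Kout_Drug"}

_BLOCK_TYPES = {"plasma": PlasmaParams, "tumor": TumorDistParams,
                "cell": CellParams, "pd": PDParams}


def _build_block(cls, entries: dict[str, Any]):
    kwargs: dict[str, float] = {}
    for key, entry in entries.items():
        value = entry["value"] if isinstance(entry, dict) else entry
        if key.endswith("_per_h"):
            key = key[: -len("_per_h")]
            value = per_hour_to_per_day(float(value))
        known = {f.name for f in dataclasses.fields(cls)}
        if key not in known:
            raise UnitError(f"unknown parameter '{key}' for {cls.__name__}")
        kwargs[key] = float(value)
    return cls(**kwargs)


def load_parameters(path_or_dict, model: str | None = None) -> ParameterSet:
    """Load a :class:`ParameterSet` from a YAML file or a parsed dict.

    The file holds the shared blocks plus per-model overrides under
    ``models:`` (antigen count, doubling time).  ``model`` selects one.
    """
    if isinstance(path_or_dict, dict):
        doc = path_or_dict
    else:
        with open(path_or_dict) as fh:
            doc = yaml.safe_load(fh)
    blocks = {}
    for block, cls in _BLOCK_TYPES.items():
        blocks[block] = _build_block(cls, doc.get(block, {}))
    ps = ParameterSet(**blocks, name=doc.get("name", "custom"))
    models = doc.get("models", {})
    if model is not None:
        if model not in models:
            raise UnitError(f"unknown tumor model '{model}'; have {sorted(models)}")
        overrides = models[model]
        ps = ps.replace(name=model, **{
            blk: {k.replace("_per_h", ""): v["value"] if isinstance(v, dict) else v
                  for k, v in entries.items()}
            for blk, entries in overrides.items()
        })
    return ps


def default_parameters(model: str = "n87") -> ParameterSet:
    """The bundled published parameter set for the T-vc-MMAE case study.

    ``model`` is ``"n87"`` (high-HER2 gastric carcinoma xenograft) or
    ``"mcf7"`` (low-HER2 GFP-MCF7 breast carcinoma xenograft).
    """
    ref = importlib.resources.files("adcpkpd").joinpath("data/t_vc_mmae.yaml")
    with importlib.resources.as_file(ref) as path:
        return load_parameters(path, model=model)


def save_parameters(ps: ParameterSet, path) -> None:
    """Serialize a parameter set (values in internal per-day units)."""
    doc = {"name": ps.name}
    for block in _BLOCK_TYPES:
        doc[block] = dataclasses.asdict(getattr(ps, block))
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
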