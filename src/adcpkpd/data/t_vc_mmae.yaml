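# Published parameter set for the trastuzumab-vc-MMAE case study.
# Each entry: value, unit, source (estimated = fitted to the in-vivo data,
# with CV% where reported; literature = fixed a priori; assumed = not stated
# in the source and chosen here, config-overridable).
# Fields with a _per_h suffix are converted to 1/day at load time.
name: t_vc_mmae

plasma:
  CL_ADC:   {value: 0.033,  unit: L/day/kg, source: estimated, cv_pct: 4.8}
  CLD_ADC:  {value: 0.0585, unit: L/day/kg, source: estimated, cv_pct: 12.6}
  V1_ADC:   {value: 0.084,  unit: L/kg,     source: estimated, cv_pct: 7.3}
  V2_ADC:   {value: 0.051,  unit: L/kg,     source: estimated, cv_pct: 5.2}
  CL_Drug:  {value: 18.40,  unit: L/day/kg, source: literature}
  CLD_Drug: {value: 1.84,   unit: L/day/kg, source: literature}
  V1_Drug:  {value: 0.136,  unit: L/kg,     source: literature}
  V2_Drug:  {value: 0.523,  unit: L/kg,     source: literature}
  Kdec_P:   {value: 0.323,  unit: 1/day,    source: estimated, cv_pct: 8.8}
  DAR0:     {value: 4.0,    unit: mol drug / mol antibody, source: measured}

tumor:
  R_cap:    {value: 8.0,    unit: um,      source: literature}
  R_Krogh:  {value: 75.0,   unit: um,      source: literature}
  P_ADC:    {value: 334.0,  unit: um/day,  source: literature}
  P_Drug:   {value: 21000.0, unit: um/day, source: literature}
  D_ADC:    {value: 0.022,  unit: cm^2/day, source: literature}
  D_Drug:   {value: 0.25,   unit: cm^2/day, source: literature}
  eps_ADC:  {value: 0.24,   unit: dimensionless, source: literature}
  eps_Drug: {value: 0.44,   unit: dimensionless, source: literature}

cell:
  Kon_ADC_per_h:  {value: 0.03,   unit: 1/nM/h, source: literature}
  Koff_ADC_per_h: {value: 0.014,  unit: 1/h,    source: literature}
  Kint_ADC_per_h: {value: 0.11,   unit: 1/h,    source: literature}
  Kdeg_ADC_per_h: {value: 0.353,  unit: 1/h,    source: literature}
  Kon_Tub_per_h:  {value: 0.0183, unit: 1/nM/h, source: literature}
  Koff_Tub_per_h: {value: 0.545,  unit: 1/h,    source: literature}
  Tub_tot_conc:   {value: 65.0,   unit: nM,     source: literature}
  Kin_Drug_per_h: {value: 8.33,   unit: 1/h,    source: literature}
  Kout_Drug_per_h: {value: 0.046, unit: 1/h,    source: literature}
  Ag_ex:          {value: 185000.0, unit: receptors/cell, source: estimated, cv_pct: 2.8}
  V_cell:         {value: 1.0e-12, unit: L/cell, source: assumed}
  cells_per_mm3:  {value: 1.0e+5,  unit: cells/mm^3, source: assumed}  # 1e8 cells/g at 1 g/mL

pd:
  Kmax:   {value: 1.03,  unit: 1/day, source: estimated, cv_pct: 31.3}
  KC50:   {value: 96.8,  unit: percent occupancy, source: estimated, cv_pct: 13.2}
  gamma:  {value: 15.02, unit: dimensionless, source: estimated, cv_pct: 38.6}
  tau:    {value: 2.03,  unit: day, source: estimated}
  DT:     {value: 13.5,  unit: day, source: estimated, cv_pct: 11.4}
  TV0:    {value: 375.0, unit: mm^3, source: design}
  omega_Kmax: {value: 0.1016, unit: lognormal sd, source: estimated, cv_pct: 47}
  omega_tau:  {value: 0.194,  unit: lognormal sd, source: estimated, cv_pct: 32}

models:
  n87:
    cell: {Ag_ex: {value: 185000.0, unit: receptors/cell, source: estimated, cv_pct: 2.8}}
    pd:   {DT: {value: 13.5, unit: day, source: estimated, cv_pct: 11.4}}
  mcf7:
    cell: {Ag_ex: {value: 22400.0, unit: receptors/cell, source: estimated, cv_pct: 3.2}}
    pd:   {DT: {value: 10.6, unit: day, source: estimated, cv_pct: 18.7}}
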