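# Methods

## Model structure and unit conventions

The simulator integrates 15 states: plasma conjugate amounts (nmol per
animal) and free-payload concentrations (nM), the average DAR, the tumor
extracellular conjugate (a concentration per total tumor volume, nM) and
free payload (an amount, nmol), four per-cell species (molecules/cell),
and four tumor-volume compartments (mm³). Time is in days everywhere;
cell-level rates published per hour are multiplied by 24 once, at load
time, and a unit-audit test asserts every rate reaching the ODE
right-hand side is per day.

Published pharmacokinetic parameters are per kg while the tumor is an
absolute volume. The bridge is a body weight (default 0.02 kg,
configurable): clearances and volumes are converted to per-animal values
so that per-animal amounts, nM concentrations and litres of tumor coexist
consistently. Four constants the source model leaves unstated are
explicit, flagged assumptions: antibody molecular weight 150,000 g/mol
(IgG1 plus ~4 drug-linkers) for mg/kg → nmol conversion; cell volume 1 pL
(typical carcinoma cell), needed both for the payload influx term and to
convert the 65 nM tubulin pool to 39,144 molecules/cell; the
molecules→nmol factor SF = 1e9/N_A; and tumor density 1 g/mL so that
1e8 cells/g means 1e5 cells/mm³, matching the 10⁵ factor in the
death-release terms.

## Simulation modes

* `plasma_only` — the five plasma states, tumor decoupled. This is the
  structural model of calibration stage 1.
* `pk_only` — full coupling, kill and death-release off, tumor growing
  exponentially; initial volume 500 mm³ (the PK study condition).
* `pkpd` — occupancy-driven kill, transit compartments, and release of
  cell contents from the dying compartment; initial volume 375 mm³ (the
  TGI study condition, midpoint of the 350–400 mm³ enrolment window).

Dosing is an instantaneous bolus into the central conjugate compartment;
the integrator restarts at dose times. The solver is LSODA (the steep
Hill kill, γ ≈ 15, and the fast payload influx, 200/day, make the coupled
system stiff) with rtol 1e-8 and per-state absolute tolerances scaled by
typical magnitudes; fitting loops use rtol 1e-6, and a refinement test
checks terminal observables move < 0.1% under tighter tolerances. Stiff
solvers transiently undershoot zero: states are clamped to zero inside
the right-hand side, and trajectories are audited after integration with
a hard error beyond −1e-4 of each state's scale.

The plasma submodel is linear once the conjugated payload is tracked as
z = X·DAR, so the stage-1 predictor uses the eigendecomposition solution
of the resulting 6-state system instead of the ODE engine (~100× faster
inside the optimizer); a test pins it to the engine at 1e-5.

## Observation equations

The source model fits three analytes per matrix but never writes the
observation equations; the package defines them as: plasma total
antibody = X₁/V₁; plasma total payload = DAR·X₁/V₁ + C₁; plasma
unconjugated payload = C₁; tumor total antibody = extracellular conjugate
plus cell-associated (bound + lysosomal) conjugate scaled by
N_C·SF/TV; tumor unconjugated payload = extracellular amount/TV plus
cell free + tubulin-bound scaled likewise; tumor total payload =
unconjugated + DAR × tumor total antibody.

## Mass bookkeeping of the printed equations

Two deliberate non-conservations are reproduced as printed rather than
"fixed", and are quantified by tests:

1. **Deconjugation double-count.** The central conjugate amount and the
   DAR each decline at K_dec while free payload is re-injected once, so
   with clearances off the total payload decreases at K_dec·X₁·DAR.
   Peripheral conjugate payload is never re-injected at all.
2. **No growth dilution of the extracellular pool.** The tumor
   extracellular conjugate is a concentration per total tumor volume
   with no dilution term; a growing tumor therefore manufactures
   extracellular amount at k_g·ADC_ex·TV·DAR (~3% of the payload budget
   over 21 days at study conditions).

The closed-system conservation test consequently closes everything
(clearances, deconjugation, growth) and verifies constancy to 1e-6 while
drug still cycles through binding, internalization, degradation, tubulin
exchange and transmembrane flux. One printed term was adjusted for
dimensional consistency: the plasma-side payload exchange flux carries
the TV and 1/V₁ factors its tumor-side counterpart implies; flux
antisymmetry is asserted by test.

## Estimation

Pooled fixed-effect maximum likelihood, −2LL = Σ[(y−Y)²/Var + ln Var]
with Var = (σ_int + σ_slope·Y)² evaluated at the prediction. Per-analyte
σ_slope is profiled analytically with σ_int fixed at 0 (the generator's
error model is purely proportional, so the profile is exact); a fixed-σ
path exists for testing. Positive parameters are fit on the log scale
with Nelder-Mead, five jittered multi-starts for the plasma stage,
bounded scalar search for the antigen stage, and box bounds in log space
for the PD stage (γ bounded [1, 30] and flagged weakly identifiable —
steep Hill functions inform it poorly, so the recovery experiments fix
it). Precision is reported as CV% from the inverse finite-difference
Hessian of −2LL on the log scale; a singular Hessian yields a flagged
result without CV%. Population (mixed-effects) estimation is out of
scope: subject-level variability is simulated, never estimated.

## Synthetic designs

The generator emulates the two source study designs. PK: single
10 mg/kg dose at 500 mm³, blood at 10 min and destructive blood+tumor
sampling of n = 3 per group at 1, 3 and 7 days, three analytes per
matrix. TGI: arms of 0/3/5/10 mg/kg (low-antigen model) and 0/1/3/10
(high-antigen), n = 7, volumes on a twice-weekly grid
(days 0, 3, 7, … 48), administrative censoring above a 2500 mm³ cap.
Noise is additive Gaussian with SD = σ_int + σ_slope·Y, truncated at
zero; σ_slope defaults to 0.05 (low noise, per the recovery protocol).
Subject-level variability draws Kmax and τ log-normally with the
published omegas (10.16%, 19.4%) and applies to treated arms only.

Plasma observations are generated from the `plasma_only` model rather
than the coupled one: stage-1 refits use the standalone plasma model, and
at mouse scale a 500 mm³ tumor is a non-negligible conjugate sink
(~0.0007 L/day against ~0.0012 L/day of elimination), so coupled
generation would bias a plasma-only refit by construction rather than
measure estimator quality. Tumor observations always come from the full
coupled simulation.

What passing recovery shows — and does not. Recovery demonstrates the
estimator identifies the generating parameters under the published
designs and error model. It does not validate the model against real
biology: real tumors have heterogeneous perfusion and antigen expression,
assay error is not purely proportional, and growth is not exactly
exponential; none of these are emulated.

## Reproduction of published summaries

The day 0–7 tumor AUC ratio of total payload between the antigen levels
(~1.9-fold vs ~1.8 reported) reproduces. Two published NCA summaries of
the observed data are **not** reproducible from the printed equations at
the printed parameter values, and the package reports the honest model
values rather than tuned ones: the total-antibody tumor exposure ratio
computes to ~1.3 (reported ~12) because the ratio is bounded above by
the antigen-count ratio 185,000/22,400 ≈ 8.3 even with the extracellular
pool ignored, and the Krogh exchange rate (~1.5/day for the conjugate)
equilibrates the extracellular space with plasma within a day, adding a
large antigen-independent term to both tumors; the unconjugated-payload
ratio computes to ~3.1 (reported ~1.6) because delivery via degradation
dominates the saturable tubulin pool under the printed influx/efflux
asymmetry (K_in/K_out ≈ 181-fold intracellular partitioning).

## Problem sizes

Recovery experiments use 10 seeds throughout; the PD stage uses n = 3
subjects per arm across all eight arms (zero variability, 5% noise),
which carries the same information as n = 7 at zero IIV while keeping
the refit loop compact. The full acceptance run completes in a few
minutes on one core.

## Known limitations

Single average cell per tumor (no bystander/heterogeneous populations);
no plasma target-mediated disposition; diffusion-only tumor exchange (no
convection or lymphatics); average-DAR bookkeeping rather than
DAR-species resolution; IV bolus dosing only; no below-quantification
handling in the generator.
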