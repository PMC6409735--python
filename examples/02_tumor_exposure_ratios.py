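"""Compare tumor exposure of the three analytes between antigen levels.

Simulates both tumor models (185,000 vs 22,400 receptors/cell) at
10 mg/kg in PK mode and prints the day 0-7 tumor AUC of each analyte and
the high/low fold-difference, the model's counterpart of the reported
tumor-exposure comparison.
"""

from adcpkpd import DoseRegimen, default_parameters, simulate
from adcpkpd.nca import auc_trapezoid

reg = DoseRegimen(dose_mg_per_kg=10.0)
analytes = ("total_trastuzumab", "total_mmae", "unconjugated_mmae")
aucs = {}
for model in ("n87", "mcf7"):
    res = simulate(default_parameters(model), reg, mode="pk_only",
                   tv0=500.0, t_end=7.0, n_grid=701)
    obs = res.observables()
    for a in analytes:
        aucs[(model, a)] = auc_trapezoid(res.time, obs[("tumor", a)],
                                         0.0, 7.0)

print(f"{'analyte':22s} {'AUC high (nM*d)':>16s} {'AUC low (nM*d)':>15s} "
      f"{'fold':>6s}")
for a in analytes:
    hi, lo = aucs[("n87", a)], aucs[("mcf7", a)]
    print(f"{a:22s} {hi:16.1f} {lo:15.1f} {hi / lo:6.2f}")

print()
print("The payload analytes differ far less than the antigen counts (8.3x) "
      "because intracellular tubulin binding saturates; the antibody "
      "analyte's fold-difference is capped by the extracellular pool, which "
      "equilibrates with plasma identically in both tumors.")
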