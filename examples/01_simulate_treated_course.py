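"""Simulate a treated xenograft course and print the key readouts.

A single 10 mg/kg IV bolus of the conjugate into a mouse bearing a
375 mm^3 high-antigen (N87-like) tumor, full PK-PD coupling.  Printed:
plasma analytes over the first week, the intracellular tubulin occupancy
the PK model implies, and the tumor-volume response it drives.
"""

import numpy as np

from adcpkpd import DoseRegimen, default_parameters, simulate

ps = default_parameters("n87")
res = simulate(ps, DoseRegimen(dose_mg_per_kg=10.0), mode="pkpd",
               t_end=48.0, tv0=375.0)
obs = res.observables()

print("day  plasma_tras_nM  plasma_totMMAE_nM  occupancy_%  tumor_mm3")
for day in (0.0, 1.0, 3.0, 7.0, 14.0, 21.0, 35.0, 48.0):
    row = [np.interp(day, res.time, obs[k]) for k in
           [("plasma", "total_trastuzumab"), ("plasma", "total_mmae"),
            ("tumor", "occupancy")]]
    tv = np.interp(day, res.time, res.tv_total)
    print(f"{day:4.0f}  {row[0]:14.2f}  {row[1]:17.2f}  {row[2]:11.1f}"
          f"  {tv:9.1f}")

print()
print("The occupancy climbs above the ~97% kill threshold within days and "
      "stays there long after plasma levels collapse, which is why a single "
      "dose regresses the tumor for weeks: the payload is retained on "
      "intracellular tubulin, not in circulation.")
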