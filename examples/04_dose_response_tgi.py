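"""Dose-response of tumor growth inhibition in both tumor models.

Simulates the dose arms of the efficacy study design and prints the time
each arm takes to exceed 1000 mm^3 (infinity when the tumor never does
within the horizon), the endpoint used to summarize the in-vivo response.
"""

import math

from adcpkpd import DoseRegimen, default_parameters, simulate, time_to_volume

ARMS = {"mcf7": (0.0, 3.0, 5.0, 10.0), "n87": (0.0, 1.0, 3.0, 10.0)}

print(f"{'model':6s} {'dose mg/kg':>10s} {'TV(48d) mm^3':>13s} "
      f"{'t>1000mm^3 (d)':>15s}")
for model, doses in ARMS.items():
    ps = default_parameters(model)
    for dose in doses:
        res = simulate(ps, DoseRegimen(dose_mg_per_kg=dose), mode="pkpd",
                       t_end=48.0, tv0=375.0)
        t_cross = time_to_volume(res.time, res.tv_total, 1000.0)
        t_str = f"{t_cross:.1f}" if math.isfinite(t_cross) else "never"
        print(f"{model:6s} {dose:10.0f} {res.tv_total[-1]:13.0f} "
              f"{t_str:>15s}")

print()
print("The high-antigen model regresses at doses that only delay the "
      "low-antigen model, mirroring the dose-dependent separation of the "
      "efficacy study: identical kill parameters, different target "
      "delivery.")
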