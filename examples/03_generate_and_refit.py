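"""Generate a synthetic PK study and refit the plasma stage.

Emulates the destructive-sampling design (10 mg/kg, blood at 10 min and
at 1/3/7 days, n = 3, 5% proportional error), then refits the conjugate's
two-compartment disposition and deconjugation rate by maximum likelihood
and prints estimates next to the generating truth.
"""

from adcpkpd import PKStudyDesign, default_parameters, generate_pk_dataset
from adcpkpd.estimation import fit_plasma

truth = {"CL_ADC": 0.033, "CLD_ADC": 0.0585, "V1_ADC": 0.084,
         "V2_ADC": 0.051, "Kdec_P": 0.323}

design = PKStudyDesign(seed=7)
data = generate_pk_dataset(design)
print(f"generated {len(data)} observations "
      f"({(data['matrix'] == 'plasma').sum()} plasma rows used here)")

fit = fit_plasma(data[data["matrix"] == "plasma"],
                 default_parameters("n87"), seed=7)
print(f"\n{'parameter':10s} {'truth':>8s} {'estimate':>9s} {'CV%':>6s}")
for k, v in truth.items():
    cv = f"{fit.cv_pct[k]:.1f}" if fit.cv_pct else "--"
    print(f"{k:10s} {v:8.4f} {fit.estimates[k]:9.4f} {cv:>6s}")
print(f"\n-2LL = {fit.objective:.2f}, {fit.n_evals} model evaluations")
print("Estimates within a few percent of truth show the four-point "
      "destructive design identifies the disposition parameters despite "
      "n = 3 per time point.")
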