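"""Simulate a factorial leukocyte screen, QC it, fit the model, find the LOEC.

Six fish, two exposure durations (3 h / 19 h), with and without LPS
stimulation, concentrations 0/1/5/10 uM with a planted suppression at the
two highest doses, three technical replicate wells per treatment.
"""

from leukotox import (EffectParameters, ExperimentDesign,
                      average_technical_replicates, build_design_matrix,
                      determine_loec, fit_ols, lps_quality_control,
                      simulate_assay, standard_comparisons)
from leukotox.plate_qc import filter_valid

design = ExperimentDesign(fish_ids=tuple(f"F{i}" for i in range(1, 7)),
                          concentrations=(0.0, 1.0, 5.0, 10.0),
                          n_technical=3, endpoint="phagocytosis")
params = EffectParameters(intercept=10.0, lps_effect=3.0, time_effect=1.0,
                          conc_effects={1.0: -0.2, 5.0: -2.5, 10.0: -4.0},
                          residual_sd=0.5, technical_sd=0.3)

wells = simulate_assay(design, params, seed=21)
print(f"simulated {len(wells)} wells "
      f"({len(design.fish_ids)} fish x 2 times x 2 LPS x "
      f"{len(design.concentrations)} concentrations x {design.n_technical})")

decisions = lps_quality_control(wells)
print(f"LPS positive control: {sum(d.valid for d in decisions)}/"
      f"{len(decisions)} fish valid (stimulation exceeded technical error)")

averaged = average_technical_replicates(filter_valid(wells, decisions))
fit = fit_ols(build_design_matrix(averaged))
print(f"fitted {len(fit.columns)} coefficients, "
      f"residual SD {fit.sigma2 ** 0.5:.3f} on {fit.df_resid} df")

contrasts = standard_comparisons(fit)
print("\ncomparisons at 3 h without LPS (estimate, p):")
scenario = [r for r in contrasts
            if r.meta.get("time") == "3h" and r.meta.get("lps") == "no"]
for r in scenario:
    print(f"  {r.label:42s} {r.estimate:+.3f}  p={r.p:.2e}")

loec = determine_loec(scenario, endpoint="phagocytosis", scenario="3h/no")
print(f"\nLOEC (lowest concentration with p <= 0.05): {loec}")
print("-> the planted suppression first becomes significant at 5 uM; the "
      "small -0.2 effect at 1 uM stays inside the noise.")
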