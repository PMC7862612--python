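"""Derive the EC20 and the non-cytotoxic concentration range.

Viability is calcein signal over DAPI nuclei count, normalised to the
control; the EC20 is where the curve crosses 80% viability, and only
concentrations below it are admitted to the immune assays.
"""

from leukotox import (ExperimentDesign, ViabilityTruth, estimate_ec20,
                      noncytotoxic_range, simulate_viability,
                      viability_fraction)

grid = (0.0, 1.0, 3.0, 10.0, 30.0, 100.0)
design = ExperimentDesign(fish_ids=("F1", "F2", "F3"),
                          concentrations=grid)
truth = ViabilityTruth(ec50=20.0, hill=1.2, noise_sd=0.01)

signals = simulate_viability(design, truth, seed=8)
via = viability_fraction(signals)
one = via[(via["time"] == "3h") & (via["lps"] == "no")]
print("viability at 3 h without LPS (normalised to control):")
for r in one.itertuples():
    print(f"  {r.concentration:6.1f} uM  viability {r.viability:.3f}")

ec20 = estimate_ec20(one["concentration"], one["viability"],
                     chemical="chemX", scenario="3h/no")
print(f"\nEC20 (log-linear interpolation to the 80% crossing): {ec20} uM")
admissible = noncytotoxic_range(ec20, list(grid))
print(f"non-cytotoxic range for the immune assays: {admissible}")
print("-> concentrations at or above the EC20 are excluded so immune "
      "effects are not confounded by cell death.")
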