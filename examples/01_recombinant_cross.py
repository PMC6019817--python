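"""Recombinant-direction analysis of a simulated cross.

Simulates an F2-style cross in which a recombinant chromosome 21 carries
the benthic (high-tooth) allele, corrects tooth number for fish length,
and asks via likelihood-ratio tests whether the recombinant chromosome
behaves like a marine or a benthic chromosome.
"""
import pandas as pd

from stickleqtl import cross, simulate

# Diploid classes: MM/MB are the non-recombinant classes; RM/RB carry the
# recombinant chromosome. Here R behaves like a benthic chromosome
# (+2 teeth per benthic allele).
params = simulate.CrossSimParams(
    n_offspring=150,
    class_means={"MM": 50.0, "MB": 52.0, "RM": 52.0, "RB": 54.0},
    residual_sd=1.0,
    length_slope=1.5,  # teeth per mm of standard length
    seed=42,
)
fish = simulate.simulate_cross(params)

corrected = cross.size_correct(fish)
print(f"covariates corrected for: {corrected.covariates_used}")
print(f"reference length: {corrected.reference_length:.1f} mm")

classes = pd.Series(fish.genotype_class.values, index=fish.fish_id)
anova = cross.genotype_anova(corrected.corrected, classes, restrict=None)
print(f"\nANOVA across classes: F = {anova.F:.2f}, p = {anova.p_value:.3g}")
for cls in sorted(anova.class_means):
    print(f"  {cls}: {anova.class_means[cls]:.2f} +/- {anova.class_se[cls]:.2f} teeth"
          f" (n = {anova.class_n[cls]})")

res = cross.recombinant_direction_lrt(corrected.corrected, classes, alpha=0.01)
print(f"\nsupported direction: {res.supported_direction}")
print(f"LRT of the rejected merge: 2*dLL = {res.statistic:.1f}, df = {res.df},"
      f" p = {res.p_value:.2e}")
print("\nThe recombinant chromosome raises tooth number like a benthic")
print("chromosome: merging it with the marine classes is firmly rejected,")
print("merging with the benthic classes is not — so the causal region lies")
print("in the benthic segment of the recombinant.")
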