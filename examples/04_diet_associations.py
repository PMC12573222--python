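"""Recover an injected diet effect with the three association layers.

Injects a known log-linear effect of oil intake on ethyl-paraben into
the synthetic generator, then runs Spearman screening, mutually
adjusted regression, and g-computation, comparing the g-computation
percent change with its closed-form ground truth.
"""

import numpy as np

from biomonrisk import associations, synthetic

BETA = 0.6  # log-concentration effect per 100 g/day of oil

base = synthetic.default_population_spec(seed=0)
adult = next(s for s in base.strata if s.name == "19-64")
spec = synthetic.PopulationSpec(
    strata=[synthetic.StratumSpec("19-64", 700, adult.age_range,
                                  adult.bw_mean, adult.bw_sd,
                                  adult.ht_mean, adult.ht_sd)],
    sex_ratio_male=0.5,
    analytes=[synthetic.AnalyteSpec("EP", lod=0.02, loq=0.06,
                                    geometric_mean=0.97, geometric_sd=2.5)],
    food_groups=list(base.food_groups),
    diet_effects={("oil", "EP"): BETA},
)
participants = synthetic.generate_population(spec, seed=1)
intakes = synthetic.generate_intakes(participants, spec, seed=2)
biomarkers = synthetic.generate_biomarkers(participants, spec, intakes, seed=3)
adjusted = biomarkers.assign(
    adjusted=biomarkers.raw_concentration / biomarkers.creatinine
)

screen = associations.spearman_matrix(adjusted, intakes, "EP")
oil_rho = next(r for r in screen if r.food_group == "oil")
print(f"Spearman screen, oil: rho = {oil_rho.estimate:.3f}, "
      f"p = {oil_rho.p_value:.2e}")

significant = [r.food_group for r in screen if r.p_value < 0.05]
mlr, fit = associations.mlr_food_groups(
    adjusted, intakes, participants, "EP", significant
)
oil_beta = next(r for r in mlr if r.food_group == "oil")
print(f"adjusted regression, oil: beta = {oil_beta.estimate:.3f} "
      f"ug/g-cre per g/day (R^2 = {fit['r_squared']:.2f})")

eff = associations.gcomputation_effect(
    adjusted, intakes, participants, "EP", "oil", n_boot=500, seed=4
)
truth = 100 * (np.mean(np.exp(BETA * intakes.oil.to_numpy() / 100)) - 1)
print(f"g-computation, oil: {eff.percent_change:+.1f}% "
      f"(95% CI {eff.ci_low:+.1f} to {eff.ci_high:+.1f}, p = {eff.p_value:.3f})")
print(f"closed-form ground truth: {truth:+.1f}%")
# The Spearman screen flags the oil-EP association, the regression
# quantifies it per gram of intake, and the g-computation recovers the
# injected population-average percent change within its bootstrap CI.
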