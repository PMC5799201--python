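"""Simulate a multi-cohort dataset with known truth and recover the effect.

Draws a "paper_like" dataset — the four real 25(OH)D instruments, eight
outcome cohorts totalling 12,488 glioma cases and 18,169 controls, true
causal OR 0.62 per unit of the exposure score — then runs the full
harmonise -> estimate-per-cohort -> pool chain for all three estimators.
"""

import math

from summr import (egger_regression, fixed_effect_meta, group_outcomes,
                   harmonize_dataset, ivw_estimate, mle_estimate,
                   orient_increasing, scenario_presets, simulate_dataset)

config = scenario_presets("paper_like")
dataset = simulate_dataset(config, seed=42)
print(f"true causal OR: {math.exp(dataset.truth['true_beta']):.2f}")

per_cohort = {"IVW": [], "MLE": []}
for (cohort, subtype), records in sorted(group_outcomes(dataset.outcomes).items()):
    instruments = orient_increasing(
        harmonize_dataset(list(dataset.exposures), records))
    per_cohort["IVW"].append((cohort, ivw_estimate(instruments)))
    per_cohort["MLE"].append((cohort, mle_estimate(instruments)))
    egger = egger_regression(instruments)

print(f"\n{'method':<8}{'OR':>6}{'95% CI':>15}{'P':>8}   (pooled over 8 cohorts)")
for method, components in per_cohort.items():
    pooled = fixed_effect_meta(components).pooled
    print(f"{method:<8}{pooled.or_:>6.2f}"
          f"{pooled.ci_low:>7.2f}-{pooled.ci_high:.2f}{pooled.p:>8.3f}")
# Both pooled ORs should land near the generating value 0.62; the last
# cohort's Egger regression gives a pleiotropy check on 4 SNPs (wide, since
# the intercept costs one of only four degrees of freedom):
print(f"Egger intercept (one cohort): {egger.intercept.estimate:+.3f} "
      f"(P {egger.intercept.p:.2f}) -> no detectable directional pleiotropy")
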