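"""Built-in 25(OH)D instruments, instrument strength, and allele harmonisation.

Prints the four-SNP instrument set (per-allele effects of the vitamin
D-decreasing allele on serum 25(OH)D), recomputes each SNP's F-statistic
from its effect and SE, and shows how an outcome record reported with
respect to the opposite allele is aligned before estimation.
"""

from summr import (OutcomeAssociation, builtin_sunlight_instruments,
                   f_statistic, harmonize_pair)

instruments = builtin_sunlight_instruments()
print(f"{'SNP':<12}{'locus':<10}{'pathway':<12}{'beta':>8}{'SE':>7}{'F':>7}  F=(beta/SE)^2")
for snp in instruments:
    print(f"{snp.snp_id:<12}{snp.locus:<10}{snp.pathway.value:<12}"
          f"{snp.beta_exposure:>8.3f}{snp.se_exposure:>7.3f}{snp.f_stat:>7.2f}"
          f"  {f_statistic(snp.beta_exposure, snp.se_exposure):>7.2f}")

# An outcome study reporting the GC variant with swapped effect/other
# alleles: harmonisation refers its log-OR back to the exposure's effect
# allele by negating it.
gc = instruments[0]
reported = OutcomeAssociation("rs2282679", "T", "G", beta_outcome=0.021,
                              se_outcome=0.035, cohort="UK")
pair = harmonize_pair(gc, reported)
print(f"\noutcome reported for allele T: log-OR +0.021")
print(f"after harmonisation to allele {gc.effect_allele}: log-OR {pair.y:+.3f} "
      f"(action: {pair.action.value})")
# A negative aligned y for a 25(OH)D-decreasing allele means lower vitamin D,
# lower risk on this SNP; the causal estimators weigh all SNPs together.
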