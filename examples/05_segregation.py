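"""Cohort segregation: recessive concordance, carrier frequency, LD.

Checks candidate variants against genotyping cohorts: every case must be
homozygous mutant and no control may be (full-penetrance recessive
concordance), then reports the carrier frequency among breed controls and
the genotype-dosage r-squared between the two linked candidates.
"""

from recessmap.segregation import (carrier_frequency, format_percent, genotype_r2,
                                   recessive_concordance)
from recessmap.simulate import (SimConfig, simulate_cohort,
                                simulate_validation_cohort, simulate_variants)

cfg = SimConfig(seed=42)
_, truth = simulate_cohort(cfg)
simulate_variants(cfg, truth)
cohort = simulate_validation_cohort(cfg, truth)

for vid, gt in sorted(cohort.tables.items()):
    ok, violations = recessive_concordance(gt)
    cf = carrier_frequency(gt, "breed_controls")
    print(f"{vid}: concordant={ok} (violations={violations}), "
          f"breed-control carrier frequency {format_percent(cf)}")

r2 = genotype_r2(cohort.dosages[truth.causal_variant_id],
                 cohort.dosages[truth.passenger_variant_id])
print(f"causal-vs-passenger genotype r2 = {r2:.3f}  (1.0 = perfect LD)")
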