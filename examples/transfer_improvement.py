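"""Score the growth-rate improvement after a culture transfer.

%P = (mu_max2 - mu_max1)/mu_max1 * 100 compares the maximum specific
growth rate before and after re-inoculating into the same medium.
Wells that grew only after transfer give an infinite ratio; those are
substituted with the dataset's maximum finite %P.
"""

import numpy as np

from robustpheno import (
    EffectModel,
    make_perturbation_space,
    make_transfer_records,
    resolve_infinities,
    simulate_phenotype_table,
    transfer_summary,
)

strains = [f"strain_{i:02d}" for i in range(1, 25)]
conditions = make_perturbation_space(29, seed=9)
model = EffectModel.uniform(strains, noise_cv=0.15, seed=9)
first = simulate_phenotype_table(strains, conditions, 3, model).table

# second cultivation: 30% faster on average, with replicate noise
rng = np.random.default_rng(10)
second = first.loc[first["phenotype"] == "mu_max"].copy()
second["value"] *= 1.3 * rng.lognormal(sigma=0.1, size=len(second)) / np.exp(0.005)

records = resolve_infinities(make_transfer_records(first, second))
summary = transfer_summary(records, thresholds=(20.0, 50.0))

print(f"{len(records)} transfer records "
      f"({int(records['substituted'].sum())} infinite ratios substituted)")
print("\nper-strain mean %P (first three strains):")
print(summary.per_strain.head(3).to_string(index=False))
print("\nfirst vs second cultivation Spearman correlation per group:")
print(summary.per_group[["group", "spearman_r", "p_value"]].to_string(index=False))
print(f"\nstrains with >= 20% mean improvement: "
      f"{summary.threshold_counts[20.0]} of {len(strains)}; "
      f">= 50%: {summary.threshold_counts[50.0]}")
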