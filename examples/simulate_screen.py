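"""Simulate a perturbation screen with known ground truth.

Builds the default study design — 24 strains x 29 perturbation
conditions (six groups) x 3 replicates x 5 phenotypes — and prints the
table layout plus the generative truth used by recovery tests.
"""

from robustpheno import (
    EffectModel,
    make_perturbation_space,
    simulate_phenotype_table,
)

strains = [f"strain_{i:02d}" for i in range(1, 25)]
conditions = make_perturbation_space(29, seed=1)
model = EffectModel.uniform(strains, noise_cv=0.2, seed=1)
dataset = simulate_phenotype_table(strains, conditions, n_replicates=3, model=model)

groups = sorted({c.group for c in conditions})
print(f"perturbation space: {len(conditions)} conditions in groups {groups}")
print(f"phenotype table: {len(dataset.table)} records "
      f"(= 24 strains x 29 conditions x 3 replicates x 5 phenotypes)")
print()
print(dataset.table.head(5).to_string(index=False))
print()
print("ground truth (per strain x phenotype):")
print(dataset.truth.head(5).to_string(index=False))
print()
print("'robustness' is the analytic negative Fano factor / grand mean the")
print("pipeline should recover from the sampled values.")
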