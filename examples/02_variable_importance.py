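"""Recover the informative variable from a health-record-like table.

Generates a 41-variable dataset shaped like screening data — 16 minority
records against 7,379 majority records (0.2% prevalence) with one
informative age-like variable — fits HUSDOS-Boost, and prints the top of
the vote-weighted variable-importance ranking. The importances are each
variable's share of the ensemble's total impurity decrease; they sum to 1,
and "age" should rank at or near the top.
"""

import logging

import husdosboost as hb

logging.disable(logging.WARNING)

dataset, truth = hb.generate_hr_like(seed=0)
part = hb.partition_classes(dataset)
print(f"{part.n_min} minority / {part.n_maj} majority "
      f"({hb.imbalance_ratio(part):.1f}% imbalance), "
      f"{len(dataset.schema.variables)} variables")

model = hb.fit(dataset, hb.BoostConfig(seed=0))
report = hb.variable_importance(model)

print("\ntop 10 variables by importance:")
for name, vi in report.ranked()[:10]:
    marker = "  <- informative" if name in truth.informative else ""
    print(f"  {name:<12} {vi:.4f}{marker}")
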