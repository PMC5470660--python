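"""Fit and evaluate the green/yellow/red decision-assistance model.

Green flags mark dogs inside a z-score zone that contained only later-
qualified dogs in the development sample; red flags the analogous
withdrawn-only zone; yellow flags dogs whose fitted withdrawal
probability exceeds 50% but who fall short of the red cut-off.  Green
applies from 5 months, red/yellow at 8 and 12 months only.
"""

from pupscales import (
    GeneratorConfig, generate_cohort, build_scale_scores, filter_by_outcome,
    fit_thresholds, assign_flags, evaluate_flags, weeks_saved, fit_zscores,
)
from pupscales.items import ITEM_SIGN, SCALE_ITEMS, TRAITS
from pupscales.scales import ScaleDefinition

cohort, _ = generate_cohort(GeneratorConfig(n_dogs=1000, seed=3))
scales = [
    ScaleDefinition(t, SCALE_ITEMS[t],
                    {i: "+" if ITEM_SIGN[i] > 0 else "-" for i in SCALE_ITEMS[t]})
    for t in TRAITS
]
dev = filter_by_outcome(cohort, {"qualified", "withdrawn_behaviour"})
scores = build_scale_scores(scales, dev)
z = {s: fit_zscores(scores, dev.dogs, s).z for s in ("whole", "breed", "breed_sex")}

thresholds = fit_thresholds(z, dev.outcome_of(), min_support=5)
flags = assign_flags(z, thresholds)
evaluation = evaluate_flags(flags, dev).set_index("flag")

for colour in ("green", "red", "yellow"):
    row = evaluation.loc[colour]
    print(f"{colour:>6}: {row.n_flagged:>3} dogs flagged "
          f"({row.n_qualified} qualified, {row.n_withdrawn_behaviour} withdrawn); "
          f"PPV {100 * row.ppv:.1f}%, sensitivity {100 * row.sensitivity:.0f}%")

print("\n(PPV here follows the development study's definition: correctly")
print("predicted dogs over all cohort dogs with that outcome; sensitivity")
print("is correct predictions over all dogs given that flag.)")

pw, tr = weeks_saved(flags, dev)
print(f"\nwithdrawing red-flagged dogs at flag time would have saved "
      f"{pw:.0f} puppy-walking and {tr:.0f} formal-training weeks")
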