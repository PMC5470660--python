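"""Evaluate reliability and validity of the questionnaire scales.

Temporal consistency (Spearman > 0.30 acceptable), construct validity
(|rho| > 0.40 with the predicted sign), predictive regressions (odds
ratios per mm, breed/sex-adjusted) and concurrent associations with
behaviour-test measures.
"""

from pupscales import GeneratorConfig, generate_cohort, build_scale_scores, filter_by_outcome
from pupscales.items import ITEM_SIGN, SCALE_ITEMS, TRAITS
from pupscales.scales import ScaleDefinition
from pupscales.synthetic import MEASURE_TABLE
from pupscales.validity import (
    DEFAULT_CONCURRENT_HYPOTHESES, DEFAULT_CONSTRUCT_HYPOTHESES,
    association_tests, construct_matrix, mean_temporal_rho, or_to_percent,
    regression_table, temporal_consistency,
)

cohort, _ = generate_cohort(GeneratorConfig(n_dogs=1200, seed=2))
scales = [
    ScaleDefinition(t, SCALE_ITEMS[t],
                    {i: "+" if ITEM_SIGN[i] > 0 else "-" for i in SCALE_ITEMS[t]})
    for t in TRAITS
]
scores = build_scale_scores(scales, cohort)

consistency = temporal_consistency(scores)
print("mean cross-scale rank stability per age pair (>0.30 acceptable):")
print(mean_temporal_rho(consistency).round(2).to_string())

_, verdicts = construct_matrix(
    scores[scores.age_point == "12M"], DEFAULT_CONSTRUCT_HYPOTHESES
)
print(f"\nconstruct hypotheses accepted (|rho|>0.40, sign match): "
      f"{int(verdicts.accepted.sum())}/{len(verdicts)}")

dev = filter_by_outcome(cohort, {"qualified", "withdrawn_behaviour"})
reg = regression_table(scores, dev)
sig = reg[reg.p < 0.05]
print(f"\nscale x age regressions significant at p<0.05: {len(sig)}/{len(reg)}")
row = reg[(reg.scale == "General Anxiety") & (reg.age_point == "8M")].iloc[0]
print(f"General Anxiety at 8M: OR {row.odds_ratio:.3f}/mm "
      f"= {or_to_percent(row.odds_ratio):+.1f}% withdrawal odds per mm")

kinds = {m: k for m, (k, _, _) in MEASURE_TABLE.items()}
assoc = association_tests(
    DEFAULT_CONCURRENT_HYPOTHESES,
    cohort.test_records.query("age_point == '8M'"),
    scores[scores.age_point == "8M"],
    kinds,
)
print(f"\nconcurrent predictions supported at 8M: "
      f"{int(assoc.supported.sum())}/{len(assoc)} "
      f"({int(assoc.opposite_direction.sum())} significant but opposite)")
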