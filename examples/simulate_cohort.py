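"""Generate a synthetic cohort of juvenile guide dogs and inspect it.

The generator emulates the structure the analysis assumes: seven
correlated latent traits per dog with calibrated age-to-age stability,
VAS item responses in millimetres, breed/sex shifts, outcome assignment
through a logistic link, monotone attrition and 'Not Known' missingness.
"""

from pupscales import GeneratorConfig, generate_cohort

cohort, truth = generate_cohort(GeneratorConfig(n_dogs=1000, seed=42))

print(f"dogs: {cohort.n_dogs}, item responses: {cohort.n_responses}")
print("\nfinal outcomes (the logistic link targets ~32% behavioural")
print("withdrawal among behaviour-decided dogs):")
print(cohort.dogs["outcome"].value_counts().to_string())

beh = cohort.dogs[cohort.dogs.outcome.isin(["qualified", "withdrawn_behaviour"])]
frac = (beh.outcome == "withdrawn_behaviour").mean()
print(f"\nwithdrawn-for-behaviour fraction among decided dogs: {frac:.3f}")

per_age = cohort.responses.groupby("age_point")["dog_id"].nunique()
print("\ndogs assessed per age point (attrition is monotone):")
print(per_age.reindex(["5M", "8M", "12M"]).to_string())

# ground truth is retained for recovery tests
print("\ntrue latent traits for the first dog (SD units):")
print(truth.latents.iloc[0].unstack().round(2))
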