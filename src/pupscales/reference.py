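"""Published reference statistics from the development cohort.

The questionnaire and flag system were developed on a single cohort of
1,401 juvenile guide dogs assessed at 5, 8 and 12 months.  The raw data
are not available, but the development report prints summary statistics
that this package uses as worked-example inputs (odds ratios for the
odds-to-percent conversion, flag counts for the evaluation metrics) and
as calibration targets for the synthetic-cohort generator (internal
reliabilities, cross-age rank stabilities, outcome composition).
"""

from __future__ import annotations

#: Dogs per final outcome in the development cohort (n = 1,401).
OUTCOME_COUNTS: dict[str, int] = {
    "qualified": 816,
    "withdrawn_behaviour": 384,
    "withdrawn_health": 103,
    "breeding": 74,
    "withdrawn_health_behaviour": 8,
    "transferred": 8,
    "died": 8,
}

#: Breed composition (sire x dam crosses) of the development cohort.
#: The printed per-breed counts sum to 1,385; they are used as
#: proportional weights.
BREED_COUNTS: dict[str, int] = {
    "GRxLab": 469,
    "Lab": 401,
    "LabxGRcross": 131,
    "GR": 128,
    "LabxGR": 63,
    "GSD": 51,
    "GRxGSD": 88,
    "LabxLabcross": 25,
    "GRxGRcross": 15,
    "GRxFCR": 14,
}

#: Cronbach's alpha per scale per age (internal reliability).
ALPHA_BY_AGE: dict[str, dict[str, float]] = {
    "Trainability": {"5M": 0.82, "8M": 0.87, "12M": 0.88},
    "Distractibility": {"5M": 0.85, "8M": 0.84, "12M": 0.84},
    "General Anxiety": {"5M": 0.84, "8M": 0.85, "12M": 0.83},
    "Excitability": {"5M": 0.79, "8M": 0.80, "12M": 0.80},
    "Stair Anxiety": {"5M": 0.79, "8M": 0.83, "12M": 0.84},
    "Adaptability": {"5M": 0.76, "8M": 0.74, "12M": 0.79},
    "Body Sensitivity": {"5M": 0.55, "8M": 0.56, "12M": 0.62},
}

#: Spearman rank stability of scale scores between age pairs.
TEMPORAL_RHO: dict[str, dict[tuple[str, str], float]] = {
    "Trainability": {("5M", "8M"): 0.63, ("8M", "12M"): 0.69, ("5M", "12M"): 0.55},
    "Distractibility": {("5M", "8M"): 0.57, ("8M", "12M"): 0.56, ("5M", "12M"): 0.43},
    "General Anxiety": {("5M", "8M"): 0.53, ("8M", "12M"): 0.59, ("5M", "12M"): 0.42},
    "Excitability": {("5M", "8M"): 0.62, ("8M", "12M"): 0.68, ("5M", "12M"): 0.51},
    "Stair Anxiety": {("5M", "8M"): 0.56, ("8M", "12M"): 0.63, ("5M", "12M"): 0.44},
    "Adaptability": {("5M", "8M"): 0.60, ("8M", "12M"): 0.63, ("5M", "12M"): 0.51},
    "Body Sensitivity": {("5M", "8M"): 0.57, ("8M", "12M"): 0.65, ("5M", "12M"): 0.50},
}

#: Mean cross-scale temporal stability per age pair.
MEAN_TEMPORAL_RHO: dict[tuple[str, str], float] = {
    ("5M", "8M"): 0.58,
    ("8M", "12M"): 0.63,
    ("5M", "12M"): 0.48,
}

#: Odds ratios from the 21 published univariate logistic regressions of
#: training outcome (qualified vs withdrawn for behaviour) on raw scale
#: score (per mm), adjusted for breed and sex.  Non-significant models
#: (Distractibility at 5M and 8M) reported no OR.  The printed 8M
#: Adaptability OR (0.098) is inconsistent with its own CI
#: (0.974, 0.987) and is corrected here to 0.978.
ODDS_RATIOS: dict[tuple[str, str], float] = {
    ("Trainability", "5M"): 0.980,
    ("General Anxiety", "5M"): 1.015,
    ("Adaptability", "5M"): 0.992,
    ("Excitability", "5M"): 1.013,
    ("Stair Anxiety", "5M"): 1.009,
    ("Body Sensitivity", "5M"): 1.021,
    ("Trainability", "8M"): 0.980,
    ("General Anxiety", "8M"): 1.023,
    ("Adaptability", "8M"): 0.978,
    ("Excitability", "8M"): 1.015,
    ("Stair Anxiety", "8M"): 1.010,
    ("Body Sensitivity", "8M"): 1.022,
    ("Trainability", "12M"): 0.978,
    ("Distractibility", "12M"): 1.008,
    ("General Anxiety", "12M"): 1.027,
    ("Adaptability", "12M"): 0.977,
    ("Excitability", "12M"): 1.016,
    ("Stair Anxiety", "12M"): 1.010,
    ("Body Sensitivity", "12M"): 1.024,
}

#: Flag counts from applying the recommended thresholds to the full
#: cohort (green from 5/8/12M scores; red and yellow from 8/12M only).
FLAG_COUNTS: dict[str, dict[str, int]] = {
    "green": {"qualified": 69, "withdrawn_behaviour": 12},
    "red": {"withdrawn_behaviour": 32, "qualified": 10},
    "yellow": {"withdrawn_behaviour": 72, "qualified": 68},
}

#: Cumulative weeks of rearing/training time that earlier withdrawal of
#: red-flagged dogs would have saved.
WEEKS_SAVED = {"puppy_walking": 499, "formal_training": 258}
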