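"""Catalogue of the 39 questionnaire items and the seven trait scales.

Each item is scored on a 100 mm visual analogue scale.  35 items belong
to one of seven trait scales; four are miscellaneous and carried through
unscored.  ``direction`` is the item's keying within its scale: ``+``
items increase with the trait, ``-`` items are reverse-keyed (scored as
100 minus the raw value before averaging).  Seven items are
reverse-keyed: six in Trainability and one in Excitability.
"""

from __future__ import annotations

import pandas as pd

TRAITS: tuple[str, ...] = (
    "Trainability",
    "General Anxiety",
    "Adaptability",
    "Excitability",
    "Body Sensitivity",
    "Distractibility",
    "Stair Anxiety",
)

MISC = "Miscellaneous"

# item_id, scale, direction  ("NA" direction for miscellaneous items)
_ITEM_ROWS: list[tuple[str, str, str]] = [
    # Trainability (6 reverse-keyed, 7 positive)
    ("loses_interest_quickly", "Trainability", "-"),
    ("easily_distracted_attention", "Trainability", "-"),
    ("stubborn", "Trainability", "-"),
    ("seems_not_to_listen", "Trainability", "-"),
    ("refuses_learned_commands", "Trainability", "-"),
    ("needs_commands_repeated", "Trainability", "-"),
    ("attentive_to_you", "Trainability", "+"),
    ("rapid_response_to_correction", "Trainability", "+"),
    ("easy_to_control", "Trainability", "+"),
    ("eager_to_please", "Trainability", "+"),
    ("friendly", "Trainability", "+"),
    ("stays_when_instructed", "Trainability", "+"),
    ("immediate_recall_off_lead", "Trainability", "+"),
    # General Anxiety
    ("startled_by_sounds", "General Anxiety", "+"),
    ("startled_by_objects", "General Anxiety", "+"),
    ("anxious_in_new_situations", "General Anxiety", "+"),
    ("reluctant_to_pass_street_objects", "General Anxiety", "+"),
    # Adaptability
    ("adapts_to_new_environments", "Adaptability", "+"),
    ("recovers_quickly_when_unsettled", "Adaptability", "+"),
    # Excitability
    ("excited_somewhere_new", "Excitability", "+"),
    ("excited_when_you_enter_home", "Excitability", "+"),
    ("active_and_energetic", "Excitability", "+"),
    ("mischievous", "Excitability", "+"),
    ("calm_and_quiet", "Excitability", "-"),
    ("initially_excitable_settles", "Excitability", "+"),
    # Body Sensitivity
    ("uneasy_being_handled", "Body Sensitivity", "+"),
    ("uneasy_with_equipment", "Body Sensitivity", "+"),
    ("reluctant_to_walk_close", "Body Sensitivity", "+"),
    # Distractibility
    ("pulls_towards_dogs", "Distractibility", "+"),
    ("pulls_towards_food", "Distractibility", "+"),
    ("interest_passing_people", "Distractibility", "+"),
    ("interest_encountering_dogs", "Distractibility", "+"),
    ("sniffs_street_objects", "Distractibility", "+"),
    # Stair Anxiety
    ("uneasy_closed_stairs", "Stair Anxiety", "+"),
    ("uneasy_open_stairs", "Stair Anxiety", "+"),
    # Miscellaneous (unscored)
    ("requires_indoor_kennel", MISC, "NA"),
    ("accepts_decision_making", MISC, "NA"),
    ("looks_when_spoken_to", MISC, "NA"),
    ("interest_when_approached", MISC, "NA"),
]

ITEM_TABLE: pd.DataFrame = pd.DataFrame(
    _ITEM_ROWS, columns=["item_id", "scale", "direction"]
)

ALL_ITEMS: tuple[str, ...] = tuple(ITEM_TABLE["item_id"])
SCALE_ITEMS: dict[str, list[str]] = {
    t: ITEM_TABLE.loc[ITEM_TABLE["scale"] == t, "item_id"].tolist() for t in TRAITS
}
MISC_ITEMS: tuple[str, ...] = tuple(
    ITEM_TABLE.loc[ITEM_TABLE["scale"] == MISC, "item_id"]
)
#: item -> keying sign within its scale (+1 or -1); misc items excluded.
ITEM_SIGN: dict[str, int] = {
    r.item_id: (1 if r.direction == "+" else -1)
    for r in ITEM_TABLE.itertuples()
    if r.direction in ("+", "-")
}
#: item -> owning trait scale; misc items excluded.
ITEM_TRAIT: dict[str, str] = {
    r.item_id: r.scale for r in ITEM_TABLE.itertuples() if r.scale != MISC
}
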