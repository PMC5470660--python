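"""Data model and CSV I/O for juvenile-dog questionnaire cohorts.

A cohort couples a dog registry (breed, sex, milestone dates, final
training outcome) with long-format visual-analogue-scale (VAS) item
responses collected at three age points (5, 8 and 12 months) and,
optionally, a table of coded behaviour-test measures.

VAS responses are integer millimetres in [0, 100] — the distance of the
rater's mark from the left anchor of a 100 mm line.  A rater may instead
answer "Not Known", encoded in files as the literal token ``NK`` and held
in memory as ``NaN``.  An absent row means the questionnaire for that
(dog, age) was never completed, which is distinct from ``NK``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

AGE_POINTS: tuple[str, ...] = ("5M", "8M", "12M")

#: The ten sire-by-dam breed crosses of the breeding programme.
BREEDS: tuple[str, ...] = (
    "GRxLab",
    "Lab",
    "LabxGRcross",
    "GR",
    "LabxGR",
    "GSD",
    "GRxGSD",
    "LabxLabcross",
    "GRxGRcross",
    "GRxFCR",
)

OUTCOMES: tuple[str, ...] = (
    "qualified",
    "withdrawn_behaviour",
    "withdrawn_health",
    "withdrawn_health_behaviour",
    "breeding",
    "transferred",
    "died",
)

SEXES: tuple[str, ...] = ("M", "F")

#: File token for a "Not Known" VAS response.
NOT_KNOWN = "NK"

REGISTRY_COLUMNS = [
    "dog_id",
    "breed",
    "sex",
    "birth_date",
    "training_entry_date",
    "outcome",
    "outcome_date",
]
RESPONSE_COLUMNS = ["dog_id", "age_point", "item_id", "value"]
TEST_COLUMNS = ["dog_id", "age_point", "measure_id", "value"]


class CohortError(ValueError):
    """Raised when a cohort file or table violates the data contract."""


@dataclass
class Cohort:
    """A dog registry plus long-format item responses.

    Attributes
    ----------
    dogs : DataFrame with :data:`REGISTRY_COLUMNS`; one row per dog.
    responses : DataFrame with :data:`RESPONSE_COLUMNS`; ``value`` is
        float millimetres, ``NaN`` meaning "Not Known".
    test_records : optional DataFrame with :data:`TEST_COLUMNS` of coded
        behaviour-test measures (mixed numeric/categorical values).
    """

    dogs: pd.DataFrame
    responses: pd.DataFrame
    test_records: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.dogs = self.dogs.reset_index(drop=True)
        self.responses = self.responses.reset_index(drop=True)
        validate_cohort(self)

    @property
    def n_dogs(self) -> int:
        return len(self.dogs)

    @property
    def n_responses(self) -> int:
        return len(self.responses)

    def outcome_of(self) -> pd.Series:
        """dog_id -> outcome mapping."""
        return self.dogs.set_index("dog_id")["outcome"]

    def wide_responses(self, age_point: str) -> pd.DataFrame:
        """Pivot one age point to a dogs x items matrix (NaN = NK/absent)."""
        if age_point not in AGE_POINTS:
            raise CohortError(f"unknown age point {age_point!r}")
        sub = self.responses[self.responses["age_point"] == age_point]
        return sub.pivot(index="dog_id", columns="item_id", values="value")


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortError(f"{what} table is missing columns {missing}")


def validate_cohort(cohort: Cohort) -> None:
    dogs, responses = cohort.dogs, cohort.responses
    _require_columns(dogs, REGISTRY_COLUMNS, "registry")
    _require_columns(responses, RESPONSE_COLUMNS, "responses")

    if dogs["dog_id"].duplicated().any():
        dupes = dogs.loc[dogs["dog_id"].duplicated(), "dog_id"].tolist()
        raise CohortError(f"duplicate dog_id(s) in registry: {dupes}")
    bad_breed = set(dogs["breed"]) - set(BREEDS)
    if bad_breed:
        raise CohortError(f"unknown breed label(s): {sorted(bad_breed)}")
    bad_outcome = set(dogs["outcome"]) - set(OUTCOMES)
    if bad_outcome:
        raise CohortError(f"unknown outcome label(s): {sorted(bad_outcome)}")
    bad_sex = set(dogs["sex"]) - set(SEXES)
    if bad_sex:
        raise CohortError(f"unknown sex label(s): {sorted(bad_sex)}")

    both = dogs.dropna(subset=["birth_date", "outcome_date"])
    late = both["outcome_date"] < both["birth_date"]
    if late.any():
        raise CohortError(
            f"outcome_date precedes birth_date for {both.loc[late, 'dog_id'].tolist()}"
        )

    if len(responses):
        bad_age = set(responses["age_point"]) - set(AGE_POINTS)
        if bad_age:
            raise CohortError(f"unknown age point(s): {sorted(bad_age)}")
        unknown = set(responses["dog_id"]) - set(dogs["dog_id"])
        if unknown:
            raise CohortError(
                f"responses reference dog_id(s) absent from registry: {sorted(unknown)[:5]}"
            )
        dup = responses.duplicated(subset=["dog_id", "age_point", "item_id"])
        if dup.any():
            row = responses[dup].iloc[0]
            raise CohortError(
                "duplicate response for "
                f"(dog={row['dog_id']}, age={row['age_point']}, item={row['item_id']})"
            )
        vals = responses["value"]
        bad = vals.notna() & ((vals < 0) | (vals > 100))
        if bad.any():
            idx = int(bad.idxmax())
            raise CohortError(
                f"response value {vals[idx]} outside [0, 100] at row {idx}"
            )


def _parse_value(raw: object, row: int) -> float:
    if isinstance(raw, str):
        token = raw.strip()
        if token == NOT_KNOWN:
            return float("nan")
        try:
            return float(token)
        except ValueError:
            raise CohortError(f"unparseable response value {raw!r} at row {row}")
    return float(raw)  # type: ignore[arg-type]


def load_cohort(
    registry_path,
    responses_path,
    test_records_path=None,
) -> Cohort:
    """Load and validate a cohort from CSV files.

    ``NK`` tokens in the value column are preserved as ``NaN``; any value
    outside [0, 100], duplicate (dog, age, item), or unknown breed/outcome
    label is a hard error naming the offending row or label.
    """
    dogs = pd.read_csv(registry_path, dtype={"dog_id": str})
    _require_columns(dogs, REGISTRY_COLUMNS, "registry")
    for col in ("birth_date", "training_entry_date", "outcome_date"):
        dogs[col] = pd.to_datetime(dogs[col], format="ISO8601", errors="raise")

    responses = pd.read_csv(responses_path, dtype={"dog_id": str, "value": str})
    _require_columns(responses, RESPONSE_COLUMNS, "responses")
    responses["value"] = [
        _parse_value(v, i) for i, v in enumerate(responses["value"])
    ]

    tests = None
    if test_records_path is not None:
        tests = pd.read_csv(test_records_path, dtype={"dog_id": str})
        _require_columns(tests, TEST_COLUMNS, "test records")

    return Cohort(dogs=dogs, responses=responses, test_records=tests)


def save_cohort(cohort: Cohort, registry_path, responses_path, test_records_path=None) -> None:
    """Write a cohort back to CSV; inverse of :func:`load_cohort`."""
    dogs = cohort.dogs.copy()
    for col in ("birth_date", "training_entry_date", "outcome_date"):
        dogs[col] = pd.to_datetime(dogs[col]).dt.strftime("%Y-%m-%d")
    dogs.to_csv(registry_path, index=False)

    responses = cohort.responses.copy()
    responses["value"] = [
        NOT_KNOWN if pd.isna(v) else f"{v:g}" for v in responses["value"]
    ]
    responses.to_csv(responses_path, index=False)

    if test_records_path is not None and cohort.test_records is not None:
        cohort.test_records.to_csv(test_records_path, index=False)


def filter_by_outcome(cohort: Cohort, included: Iterable[str]) -> Cohort:
    """Restrict a cohort to dogs whose final outcome is in ``included``.

    Used to reproduce the study-design subsamples (e.g. the development
    sample keeps only dogs that qualified or were withdrawn for
    behaviour).  ``included`` must be non-empty.
    """
    included = set(included)
    if not included:
        raise CohortError("included outcome set must be non-empty")
    unknown = included - set(OUTCOMES)
    if unknown:
        warnings.warn(f"ignoring unknown outcome label(s) {sorted(unknown)}")
    keep = cohort.dogs["outcome"].isin(included)
    dogs = cohort.dogs[keep]
    ids = set(dogs["dog_id"])
    responses = cohort.responses[cohort.responses["dog_id"].isin(ids)]
    tests = None
    if cohort.test_records is not None:
        tests = cohort.test_records[cohort.test_records["dog_id"].isin(ids)].reset_index(drop=True)
    return Cohort(dogs=dogs, responses=responses, test_records=tests)
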