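"""Z-score normalisation of scale scores against reference statistics.

Scores are standardised as z = (raw - reference mean) / reference SD,
per scale and age point, under one of three grouping schemes:

``whole``
    one reference group — the whole fitting sample;
``breed``
    reference statistics within breed (controls for breed);
``breed_sex``
    reference statistics within breed-by-sex cells.

Fitted reference statistics are retained so that dogs from a new cohort
can be scored against the development population without refitting.
Sparse cells fall back: a breed-by-sex cell with fewer than
``min_group`` dogs uses its breed's statistics, and a deficient breed
cell falls back to the whole sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

SCHEMES = ("whole", "breed", "breed_sex")


class ZScoreError(ValueError):
    pass


def _group_cols(scheme: str) -> list[str]:
    if scheme == "whole":
        return []
    if scheme == "breed":
        return ["breed"]
    if scheme == "breed_sex":
        return ["breed", "sex"]
    raise ZScoreError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


@dataclass
class ZScoreSet:
    """Fitted z-scores plus the reference statistics that produced them.

    ``reference`` has one row per (group, scale, age_point) with the
    group's mean, sd (sample, n-1) and n; group columns depend on the
    scheme.  ``z`` is a long table: dog_id, age_point, scale, z.
    """

    scheme: str
    reference: pd.DataFrame
    z: pd.DataFrame
    min_group: int = 10
    fallbacks: dict = field(default_factory=dict)


def _merge_dog_groups(scores: pd.DataFrame, dogs: pd.DataFrame) -> pd.DataFrame:
    return scores.merge(dogs[["dog_id", "breed", "sex"]], on="dog_id", how="left")


def _stats(scored: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    keys = cols + ["scale", "age_point"]
    g = scored.dropna(subset=["score"]).groupby(keys)["score"]
    ref = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    return ref


def fit_zscores(
    scores: pd.DataFrame,
    dogs: pd.DataFrame,
    scheme: str = "whole",
    min_group: int = 10,
    ddof: int = 1,
) -> ZScoreSet:
    """Fit reference statistics and standardise the fitting population.

    ``scores`` is the long scale-score table (dog_id, age_point, scale,
    score); ``dogs`` supplies breed and sex.  Cells with fewer than
    ``min_group`` dogs (breed_sex scheme), or with fewer than 2 scores
    or zero SD, fall back to the coarser grouping; a zero-SD whole-
    sample cell is an error naming the cell.
    """
    cols = _group_cols(scheme)
    scored = _merge_dog_groups(scores, dogs)

    refs = {"whole": _stats(scored, [])}
    if scheme in ("breed", "breed_sex"):
        refs["breed"] = _stats(scored, ["breed"])
    if scheme == "breed_sex":
        refs["breed_sex"] = _stats(scored, ["breed", "sex"])

    whole = refs["whole"]
    bad = whole[(whole["n"] < 2) | (whole["sd"] <= 0)]
    if len(bad):
        cell = bad.iloc[0]
        raise ZScoreError(
            f"zero or undefined SD for whole-sample cell "
            f"(scale={cell['scale']}, age={cell['age_point']})"
        )

    ref = refs[scheme].copy()
    fallbacks: dict = {}
    if scheme == "breed_sex":
        ok = (ref["n"] >= min_group) & (ref["sd"] > 0)
        fallbacks["breed"] = ref.loc[~ok, ["breed", "sex", "scale", "age_point"]]
        ref = ref[ok]
    if scheme in ("breed", "breed_sex"):
        breed_ref = refs["breed"]
        ok = (breed_ref["n"] >= 2) & (breed_ref["sd"] > 0)
        fallbacks["whole"] = breed_ref.loc[~ok, ["breed", "scale", "age_point"]]
        refs["breed"] = breed_ref[ok]
        if scheme == "breed":
            ref = refs["breed"]

    zset = ZScoreSet(
        scheme=scheme,
        reference=ref.reset_index(drop=True),
        z=pd.DataFrame(),
        min_group=min_group,
        fallbacks={
            "breed": refs.get("breed"),
            "whole": refs["whole"],
        },
    )
    zset.z = apply_zscores(scores, dogs, zset, _warn_unseen=False)
    return zset


def apply_zscores(
    scores: pd.DataFrame,
    dogs: pd.DataFrame,
    zset: ZScoreSet,
    _warn_unseen: bool = True,
) -> pd.DataFrame:
    """Standardise scores against previously fitted reference statistics.

    Never refits: a dog whose breed (or breed-sex cell) has no stored
    reference falls back to the breed then whole-sample statistics, with
    a warning for unseen breeds.
    """
    cols = _group_cols(zset.scheme)
    scored = _merge_dog_groups(scores, dogs)
    out = scored.copy()
    out["z"] = float("nan")
    matched = pd.Series(False, index=out.index)

    tiers: list[tuple[list[str], pd.DataFrame]] = [(cols, zset.reference)]
    if zset.scheme == "breed_sex" and zset.fallbacks.get("breed") is not None:
        tiers.append((["breed"], zset.fallbacks["breed"]))
    if zset.scheme != "whole":
        tiers.append(([], zset.fallbacks["whole"]))

    for tier_cols, ref in tiers:
        if ref is None or ref.empty:
            continue
        keys = tier_cols + ["scale", "age_point"]
        merged = scored.merge(
            ref[keys + ["mean", "sd"]], on=keys, how="left", validate="m:1"
        )
        usable = (~matched) & merged["mean"].notna() & scored["score"].notna()
        out.loc[usable, "z"] = (
            scored.loc[usable, "score"] - merged.loc[usable, "mean"]
        ) / merged.loc[usable, "sd"]
        matched |= merged["mean"].notna()
        if tier_cols == cols and zset.scheme != "whole" and _warn_unseen:
            unseen = scored.loc[~merged["mean"].notna(), "breed"].dropna().unique()
            known = set(zset.reference["breed"]) if "breed" in zset.reference else set()
            really_unseen = [b for b in unseen if b not in known]
            if really_unseen:
                warnings.warn(
                    f"breed(s) {sorted(set(really_unseen))} not in reference; "
                    "using whole-sample statistics"
                )
    return out[["dog_id", "age_point", "scale", "z"]]
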