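"""Traffic-light decision-assistance model built on scale z-scores.

For each scale, age and z-scheme the development data yield:

* a **green** cut-off — the edge of a tail zone containing only dogs
  that later qualified ("100% correct" on the development sample);
* a **red** cut-off — the analogous pure zone of dogs later withdrawn
  for behaviour;
* a **yellow** cut-off — the z at which a univariate logistic model
  puts the probability of withdrawal at 50%; dogs beyond it but short
  of the red cut-off are flagged yellow.

The z-scheme (whole / breed / breed-sex) whose pure zone captures the
most target dogs is selected per scale x age x colour.  At assignment
time green flags apply from 5 months on, red and yellow only at 8 and
12 months; evaluation reports positive predictive value and sensitivity
using the development study's own (non-conventional, term-swapped)
definitions, alongside the conventional ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_data import AGE_POINTS, OUTCOMES, Cohort

FLAG_TARGET = {"green": "qualified", "red": "withdrawn_behaviour", "yellow": "withdrawn_behaviour"}
SCHEME_ORDER = ("whole", "breed", "breed_sex")  # tie-break preference
DEFAULT_AGE_POLICY = {
    "green": ("5M", "8M", "12M"),
    "red": ("8M", "12M"),
    "yellow": ("8M", "12M"),
}


class FlagError(ValueError):
    pass


@dataclass
class FlagThreshold:
    """A fitted cut-off for one scale x age x colour."""

    scale: str
    age_point: str
    flag: str  # green / red / yellow
    z_scheme: str
    direction: str  # "above" or "below": the side of the cutoff that is flagged
    cutoff: float | None  # None = no flag assignable (NF)
    support: int = 0


def fit_pure_cutoff(
    z: np.ndarray,
    is_target: np.ndarray,
    favorable_tail: str,
    min_support: int = 5,
) -> tuple[float | None, int]:
    """Find the pure-zone cut-off in one tail.

    The cut-off is the z of the most extreme opposite-outcome dog in
    the target tail, so the zone strictly beyond it contains only
    target-outcome dogs.  Returns (cutoff, support); cutoff is None
    when fewer than ``min_support`` target dogs lie in the pure zone.
    Equivalent to a brute-force scan over all candidate cut points.
    """
    z = np.asarray(z, float)
    is_target = np.asarray(is_target, bool)
    ok = np.isfinite(z)
    z, is_target = z[ok], is_target[ok]
    if is_target.all() or (~is_target).all():
        raise FlagError("pure cut-off needs both outcomes present")
    if favorable_tail not in ("above", "below"):
        raise FlagError(f"favorable_tail must be 'above' or 'below', got {favorable_tail!r}")
    opp = z[~is_target]
    cutoff = float(opp.max()) if favorable_tail == "above" else float(opp.min())
    in_zone = z > cutoff if favorable_tail == "above" else z < cutoff
    support = int((in_zone & is_target).sum())
    if support < min_support:
        return None, support
    return cutoff, support


def fit_yellow_cutoff(
    z: np.ndarray, withdrawn: np.ndarray, alpha: float = 0.05
) -> tuple[float | None, str | None]:
    """The z at which fitted P(withdrawn) crosses 50%.

    Fits a univariate logistic regression of withdrawal on z; the
    crossing is -intercept/slope, flagged on the side the slope points
    to.  Returns (None, None) when the slope is not significant at
    ``alpha``, the crossing lies outside the observed z range, or the
    fit does not converge.
    """
    z = np.asarray(z, float)
    withdrawn = np.asarray(withdrawn, float)
    ok = np.isfinite(z)
    z, withdrawn = z[ok], withdrawn[ok]
    if len(np.unique(withdrawn)) < 2:
        raise FlagError("yellow cut-off needs both outcomes present")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(withdrawn, sm.add_constant(z)).fit(disp=0, maxiter=200)
    except Exception:
        warnings.warn("yellow cut-off: logistic fit did not converge")
        return None, None
    b0, b1 = res.params
    if not np.isfinite(res.bse).all() or res.bse[1] > 1e3:
        warnings.warn("yellow cut-off: separation or unstable fit")
        return None, None
    if res.pvalues[1] >= alpha or b1 == 0:
        return None, None
    crossing = -b0 / b1
    if not (z.min() <= crossing <= z.max()):
        return None, None
    return float(crossing), ("above" if b1 > 0 else "below")


def select_z_scheme(candidates: dict[str, FlagThreshold | None]) -> FlagThreshold | None:
    """Pick the scheme whose pure zone supports the most target dogs.

    Ties break in the order whole > breed > breed_sex; returns None
    when no scheme yields a cut-off (NF).
    """
    if not candidates:
        raise FlagError("no candidate thresholds")
    best: FlagThreshold | None = None
    for scheme in SCHEME_ORDER:
        cand = candidates.get(scheme)
        if cand is None or cand.cutoff is None:
            continue
        if best is None or cand.support > best.support:
            best = cand
    return best


def _risk_direction(z: np.ndarray, withdrawn: np.ndarray) -> str:
    """Tail in which withdrawal risk increases: sign of the logistic slope."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(withdrawn, sm.add_constant(z)).fit(disp=0, maxiter=200)
            slope = res.params[1]
        except Exception:
            slope = np.corrcoef(z, withdrawn)[0, 1]
    return "above" if slope >= 0 else "below"


def fit_thresholds(
    z_by_scheme: dict[str, pd.DataFrame],
    outcomes: pd.Series,
    min_support: int = 5,
    scales: list[str] | None = None,
) -> list[FlagThreshold]:
    """Fit green/red/yellow thresholds for every scale x age.

    ``z_by_scheme`` maps scheme name to a long z table (dog_id,
    age_point, scale, z) for the development sample; ``outcomes`` maps
    dog_id to final outcome (qualified / withdrawn_behaviour only).
    Yellow thresholds use the red flag's selected z-scheme, falling
    back to the green flag's scheme when no red flag is assignable.
    """
    some = next(iter(z_by_scheme.values()))
    scales = scales or sorted(some["scale"].unique())
    thresholds: list[FlagThreshold] = []
    for scale in scales:
        for age in AGE_POINTS:
            per_scheme: dict[str, pd.DataFrame] = {}
            for scheme, ztab in z_by_scheme.items():
                sub = ztab[(ztab["scale"] == scale) & (ztab["age_point"] == age)]
                sub = sub.dropna(subset=["z"]).set_index("dog_id")
                sub = sub[sub.index.isin(outcomes.index)]
                per_scheme[scheme] = sub
            chosen: dict[str, FlagThreshold | None] = {}
            for flag in ("green", "red"):
                target = FLAG_TARGET[flag]
                cands: dict[str, FlagThreshold | None] = {}
                for scheme, sub in per_scheme.items():
                    if sub.empty:
                        cands[scheme] = None
                        continue
                    wb = (outcomes.loc[sub.index] == "withdrawn_behaviour").to_numpy(float)
                    z = sub["z"].to_numpy()
                    risk_tail = _risk_direction(z, wb)
                    tail = risk_tail if flag == "red" else ("below" if risk_tail == "above" else "above")
                    is_target = (outcomes.loc[sub.index] == target).to_numpy()
                    cutoff, support = fit_pure_cutoff(z, is_target, tail, min_support)
                    cands[scheme] = FlagThreshold(scale, age, flag, scheme, tail, cutoff, support)
                chosen[flag] = select_z_scheme(cands)
                thresholds.append(
                    chosen[flag]
                    or FlagThreshold(scale, age, flag, "whole", "above", None, 0)
                )
            # yellow rides on the red flag's scheme, else the green flag's
            base = chosen.get("red") or chosen.get("green")
            scheme = base.z_scheme if base else "whole"
            sub = per_scheme.get(scheme)
            if sub is None or sub.empty:
                thresholds.append(FlagThreshold(scale, age, "yellow", scheme, "above", None, 0))
                continue
            wb = (outcomes.loc[sub.index] == "withdrawn_behaviour").to_numpy(float)
            crossing, direction = fit_yellow_cutoff(sub["z"].to_numpy(), wb)
            if crossing is None:
                thresholds.append(FlagThreshold(scale, age, "yellow", scheme, "above", None, 0))
            else:
                in_zone = (
                    sub["z"] > crossing if direction == "above" else sub["z"] < crossing
                )
                thresholds.append(
                    FlagThreshold(
                        scale, age, "yellow", scheme, direction, crossing, int(in_zone.sum())
                    )
                )
    return thresholds


def _beyond(z: pd.Series, thr: FlagThreshold) -> pd.Series:
    return z > thr.cutoff if thr.direction == "above" else z < thr.cutoff


def assign_flags(
    z_by_scheme: dict[str, pd.DataFrame],
    thresholds: list[FlagThreshold],
    age_policy: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Assign flags to dogs given fitted thresholds.

    Rule 1: beyond the green cut-off -> green.  Rule 2: beyond the red
    cut-off -> red.  Rule 3: beyond the yellow crossing but not beyond
    the red cut-off -> yellow.  The age policy (default: green from 5M,
    red/yellow at 8M and 12M only) limits which assessments each colour
    may use.  Returns a long table dog_id, age_point, scale, flag, z.
    """
    age_policy = age_policy or DEFAULT_AGE_POLICY
    by_key: dict[tuple[str, str, str], FlagThreshold] = {
        (t.scale, t.age_point, t.flag): t for t in thresholds
    }
    rows = []
    for (scale, age, flag), thr in by_key.items():
        if thr.cutoff is None or age not in age_policy.get(flag, ()):
            continue
        ztab = z_by_scheme[thr.z_scheme]
        sub = ztab[(ztab["scale"] == scale) & (ztab["age_point"] == age)].dropna(subset=["z"])
        hit = _beyond(sub["z"], thr)
        if flag == "yellow":
            red = by_key.get((scale, age, "red"))
            if red is not None and red.cutoff is not None:
                redz = z_by_scheme[red.z_scheme]
                redsub = redz[(redz["scale"] == scale) & (redz["age_point"] == age)]
                red_hit_ids = set(
                    redsub.loc[_beyond(redsub["z"], red).fillna(False), "dog_id"]
                )
                hit &= ~sub["dog_id"].isin(red_hit_ids)
        flagged = sub[hit]
        for r in flagged.itertuples():
            rows.append((r.dog_id, age, scale, flag, r.z))
    out = pd.DataFrame(rows, columns=["dog_id", "age_point", "scale", "flag", "z"])
    return out.sort_values(["dog_id", "age_point", "scale", "flag"]).reset_index(drop=True)


def evaluate_flags(assignments: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Cohort-level flag metrics, one row per colour.

    A dog counts once per colour if it received one or more flags of
    that colour.  Following the development study's definitions:
    PPV = correctly predicted dogs / all cohort dogs with the target
    outcome; sensitivity = correct predictions / all dogs flagged that
    colour.  (Conventionally these names are swapped; the conventional
    values are emitted as ppv_conventional / sensitivity_conventional.)
    Outcome breakdowns cover all seven outcomes.
    """
    outcome = cohort.outcome_of()
    missing = set(assignments["dog_id"]) - set(outcome.index)
    if missing:
        raise FlagError(f"flagged dog(s) without outcome: {sorted(missing)[:5]}")
    rows = []
    for flag in ("green", "yellow", "red"):
        flagged = assignments.loc[assignments["flag"] == flag, "dog_id"].unique()
        target = FLAG_TARGET[flag]
        n_target_cohort = int((outcome == target).sum())
        counts = {o: 0 for o in OUTCOMES}
        for o, c in outcome.loc[list(flagged)].value_counts().items():
            counts[o] = int(c)
        n_flagged = len(flagged)
        correct = counts[target]
        row = {
            "flag": flag,
            "n_flagged": n_flagged,
            "target_outcome": target,
            **{f"n_{o}": c for o, c in counts.items()},
        }
        if n_flagged == 0:
            row.update(ppv=np.nan, sensitivity=np.nan,
                       ppv_conventional=np.nan, sensitivity_conventional=np.nan)
        else:
            row.update(
                ppv=correct / n_target_cohort if n_target_cohort else np.nan,
                sensitivity=correct / n_flagged,
                ppv_conventional=correct / n_flagged,
                sensitivity_conventional=(
                    correct / n_target_cohort if n_target_cohort else np.nan
                ),
            )
        rows.append(row)
    return pd.DataFrame(rows)


#: Nominal questionnaire ages in days after birth.
AGE_DAYS = {"5M": 152, "8M": 243, "12M": 365}


def weeks_saved(assignments: pd.DataFrame, cohort: Cohort) -> tuple[float, float]:
    """Time that earlier withdrawal of red-flagged dogs would have saved.

    For each red-flagged dog that was later withdrawn for behaviour,
    the (earliest) flag date is the assessment age; weeks between flag
    and training entry count as puppy-walking savings, and weeks
    between training entry and the withdrawal date as formal-training
    savings (each floored at zero).  Returns (puppy-walking weeks,
    training weeks) summed over dogs.
    """
    dogs = cohort.dogs.set_index("dog_id")
    red = assignments[assignments["flag"] == "red"]
    pw_total = tr_total = 0.0
    for dog_id, grp in red.groupby("dog_id"):
        if dog_id not in dogs.index:
            continue
        rec = dogs.loc[dog_id]
        if rec["outcome"] != "withdrawn_behaviour":
            continue
        if pd.isna(rec["birth_date"]) or pd.isna(rec["training_entry_date"]) or pd.isna(rec["outcome_date"]):
            warnings.warn(f"dog {dog_id}: missing milestone dates; excluded")
            continue
        first_age = min(grp["age_point"], key=lambda a: AGE_DAYS[a])
        flag_date = rec["birth_date"] + pd.Timedelta(days=AGE_DAYS[first_age])
        pw = max((rec["training_entry_date"] - flag_date).days, 0) / 7.0
        tr = max((rec["outcome_date"] - rec["training_entry_date"]).days, 0) / 7.0
        pw_total += pw
        tr_total += tr
    return pw_total, tr_total
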