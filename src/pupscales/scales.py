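"""Scale construction: PCA grouping, iterative alpha refinement,
reverse-key detection, mean scale scoring and the predictive item screen.

The pipeline stage works on wide dogs x items matrices of VAS responses
(one per age point).  Items are grouped by varimax-rotated principal
components (eigenvalue > 1, salience 0.40); groupings that are unstable
across ages are re-formed by a greedy Cronbach's-alpha refinement; a
grouping becomes an accepted scale only if its direction-corrected alpha
exceeds 0.70 at every age.  Finally, items with no univariate predictive
association with training outcome at any age are screened out.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_data import AGE_POINTS, Cohort, filter_by_outcome
from .items import ITEM_TRAIT


class ScaleError(ValueError):
    pass


@dataclass
class ScaleDefinition:
    """A named group of items scored as a direction-corrected mean."""

    name: str
    items: list[str]
    direction: dict[str, str]  # item -> "+" or "-"
    alpha_by_age: dict[str, float] = field(default_factory=dict)
    provenance: str = "pca"  # "pca" or "alpha_refinement"

    def __post_init__(self) -> None:
        if len(self.items) < 2:
            raise ScaleError(f"scale {self.name!r} needs >= 2 items")


@dataclass
class ComponentSolution:
    """A varimax-rotated principal-component solution."""

    loadings: pd.DataFrame  # item x retained component
    eigenvalues: np.ndarray  # all eigenvalues, descending
    n_retained: int
    converged: bool


def varimax(loadings: np.ndarray, tol: float = 1e-6, max_iter: int = 100) -> tuple[np.ndarray, bool]:
    """Kaiser-normalised varimax rotation of a loading matrix.

    Classic pairwise planar rotations (as in R's ``stats::varimax``),
    sweeping all component pairs until no rotation angle exceeds
    ``tol`` within a sweep.
    """
    L = np.asarray(loadings, float).copy()
    p, k = L.shape
    if k < 2:
        return L, True
    comm = np.sqrt((L**2).sum(axis=1))
    comm[comm == 0] = 1.0
    L = L / comm[:, None]
    converged = False
    for _ in range(max_iter):
        biggest = 0.0
        for i in range(k):
            for j in range(i + 1, k):
                x, y = L[:, i], L[:, j]
                u, v = x * x - y * y, 2.0 * x * y
                num = 2.0 * (p * (u * v).sum() - u.sum() * v.sum())
                den = p * (u * u - v * v).sum() - (u.sum() ** 2 - v.sum() ** 2)
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) <= tol:
                    continue
                biggest = max(biggest, abs(phi))
                c, s = np.cos(phi), np.sin(phi)
                L[:, i], L[:, j] = c * x + s * y, -s * x + c * y
        if biggest <= tol:
            converged = True
            break
    return L * comm[:, None], converged


def _fix_signs(L: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-|loading| item loads positive."""
    L = L.copy()
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return L


def pca_group(
    wide: pd.DataFrame, salience: float = 0.40
) -> tuple[ComponentSolution, list[list[str]]]:
    """Group items by correlation-matrix PCA at one age.

    Rows with any missing item are dropped (listwise).  Components with
    eigenvalue > 1 are retained and varimax-rotated; an item joins the
    component on which its absolute rotated loading is largest, provided
    that loading reaches ``salience`` (an item salient on several
    components is thereby kept only where it loads strongest); items
    salient nowhere stay unassigned.
    """
    data = wide.dropna()
    items = list(wide.columns)
    if len(items) < 2:
        raise ScaleError("PCA needs at least 2 items")
    if len(data) < len(items) + 1:
        raise ScaleError(
            f"PCA needs at least {len(items) + 1} complete dogs, got {len(data)}"
        )
    X = data.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        dead = [items[i] for i in np.flatnonzero(sd == 0)]
        raise ScaleError(f"zero-variance item(s): {dead}")
    R = np.corrcoef(X, rowvar=False)
    off = np.abs(R - np.eye(len(items)))
    if off.max() > 1 - 1e-10:
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ScaleError(
            f"singular correlation matrix: items {items[i]!r} and {items[j]!r} are collinear"
        )
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_ret = int((evals > 1.0).sum())
    raw = evecs[:, :n_ret] * np.sqrt(evals[:n_ret])
    rotated, converged = varimax(raw)
    rotated = _fix_signs(rotated)
    loadings = pd.DataFrame(
        rotated, index=items, columns=[f"C{j + 1}" for j in range(n_ret)]
    )
    groups: list[list[str]] = [[] for _ in range(n_ret)]
    if n_ret:
        absL = np.abs(rotated)
        best = absL.argmax(axis=1)
        for i, item in enumerate(items):
            if absL[i, best[i]] >= salience:
                groups[best[i]].append(item)
    groups = [g for g in groups if g]
    return ComponentSolution(loadings, evals, n_ret, converged), groups


def cronbach_alpha(matrix: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item var)/var(total)).

    Rows with missing values are dropped; reverse-keyed items must be
    recoded before calling.  Sample (n-1) variances.
    """
    X = pd.DataFrame(matrix).dropna().to_numpy(float)
    n, k = X.shape
    if k < 2:
        raise ScaleError("alpha needs >= 2 items")
    if n < 2:
        raise ScaleError("alpha needs >= 2 complete dogs")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ScaleError("alpha undefined: zero total-score variance")
    return k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var)


def orient_items(wide: pd.DataFrame) -> pd.DataFrame:
    """Orient a pool of items to a common direction before alpha.

    Each item is aligned with the sign of its loading on the pool's
    first principal component (sign-fixed so most items stay unflipped);
    flipped items are recoded as 100 - value.
    """
    data = wide.dropna()
    R = np.corrcoef(data.to_numpy(float), rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    pc1 = evecs[:, -1]
    if (pc1 < 0).sum() > (pc1 > 0).sum():
        pc1 = -pc1
    out = wide.copy()
    for i, item in enumerate(wide.columns):
        if pc1[i] < 0:
            out[item] = 100.0 - out[item]
    return out


def alpha_refine(
    wide: pd.DataFrame,
    gain_threshold: float = 0.05,
    candidate_floor: float = 0.70,
) -> tuple[list[list[str]], list[str]]:
    """Form item groupings from an inconsistently loading pool by greedy
    alpha refinement on reference-age data.

    Starting from the full pool, the single item whose removal most
    improves alpha is removed while the improvement exceeds
    ``gain_threshold`` (and at least two items remain); the survivors
    form a candidate grouping if their alpha clears ``candidate_floor``.
    Removed items are pooled and the procedure repeats until no further
    grouping of >= 2 items can be formed.  Returns (groupings, leftover
    items).
    """
    pool = list(wide.columns)
    groups: list[list[str]] = []
    while len(pool) >= 2:
        oriented = orient_items(wide[pool])
        current = list(pool)
        removed: list[str] = []
        while len(current) > 2:
            base = cronbach_alpha(oriented[current])
            gains = []
            for item in current:
                rest = [i for i in current if i != item]
                gains.append(cronbach_alpha(oriented[rest]) - base)
            best = int(np.argmax(gains))
            if gains[best] > gain_threshold:
                removed.append(current.pop(best))
            else:
                break
        try:
            final_alpha = cronbach_alpha(oriented[current])
        except ScaleError:
            final_alpha = float("-inf")
        if len(current) >= 2 and final_alpha > candidate_floor:
            groups.append(current)
            pool = removed
        else:
            # no reliable grouping can be formed from what is left
            return groups, current + removed
    return groups, pool


def detect_reverse_items(items: list[str], wide: pd.DataFrame) -> dict[str, str]:
    """Identify reverse-keyed items within a scale.

    An item is marked "-" iff it correlates negatively with the mean of
    the remaining (direction-corrected) items; a correlation of exactly
    zero stays "+" (reversal must be evidenced).  Because the raw
    rest-mean is uninformative when keying is nearly balanced, the rule
    is applied as a fixed-point iteration initialised from the sign of
    each item's loading on the scale's first principal component, and
    the overall orientation is chosen so that at most half the items
    are reversed.
    """
    if len(items) < 2:
        raise ScaleError("need >= 2 items to detect reverse keying")
    data = wide[items].dropna()
    X = data.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        dead = [items[i] for i in np.flatnonzero(sd == 0)]
        raise ScaleError(f"zero-variance item(s) {dead}")
    R = np.corrcoef(X, rowvar=False)
    pc1 = np.linalg.eigh(R)[1][:, -1]
    signs = np.where(pc1 < 0, -1, 1)
    for _ in range(50):
        corrected = np.where(signs < 0, 100.0 - X, X)
        new = signs.copy()
        for i in range(len(items)):
            rest = corrected[:, [j for j in range(len(items)) if j != i]].mean(axis=1)
            r = float(np.corrcoef(X[:, i], rest)[0, 1])
            new[i] = -1 if r < 0 else 1
        if (new == signs).all():
            break
        signs = new
    if (signs < 0).sum() * 2 > len(items):
        signs = -signs
    return {item: ("-" if s < 0 else "+") for item, s in zip(items, signs)}


def scale_scores(scale: ScaleDefinition, wide: pd.DataFrame) -> pd.Series:
    """Direction-corrected mean scale score per dog at one age.

    Reverse-keyed items are scored as 100 minus the raw value; the mean
    is over answered items, and the score is missing when fewer than
    half of the scale's items were answered.
    """
    present = [i for i in scale.items if i in wide.columns]
    mat = wide[present].copy()
    missing_items = len(scale.items) - len(present)
    for item in present:
        if scale.direction.get(item, "+") == "-":
            mat[item] = 100.0 - mat[item]
    answered = mat.notna().sum(axis=1)
    score = mat.mean(axis=1)
    score[answered * 2 < len(scale.items)] = np.nan
    if missing_items:
        warnings.warn(f"{missing_items} scale item(s) absent from data")
    return score.rename(scale.name)


def build_scale_scores(scales: list[ScaleDefinition], cohort: Cohort) -> pd.DataFrame:
    """Long table of scale scores: dog_id, age_point, scale, score."""
    frames = []
    for age in AGE_POINTS:
        wide = cohort.wide_responses(age)
        if wide.empty:
            continue
        for scale in scales:
            s = scale_scores(scale, wide)
            frames.append(
                pd.DataFrame(
                    {
                        "dog_id": s.index,
                        "age_point": age,
                        "scale": scale.name,
                        "score": s.to_numpy(),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["dog_id", "age_point", "scale", "score"])
    return pd.concat(frames, ignore_index=True)


def _univariate_logit_p(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
    """p-value of the slope in logit(y) ~ x; returns (p, status)."""
    if np.std(x) == 0:
        return float("nan"), "no_variance"
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.isfinite(res.bse[1]) or res.bse[1] > 1e3:
            return 0.0, "separated"
        return float(res.pvalues[1]), "ok"
    except Exception:
        return 0.0, "separated"


def item_screen(
    cohort: Cohort, items: list[str], alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Univariate predictive screen of items against training outcome.

    The cohort must contain only qualified / withdrawn-for-behaviour
    dogs.  For each item and age a univariate binary logistic regression
    of outcome on item value is fitted; an item is retained iff it is
    significant (p < ``alpha``) at one or more ages.  Perfect separation
    counts as significant and is reported as "separated".  Returns
    (retained items, per item x age p-value table).
    """
    extra = set(cohort.dogs["outcome"]) - {"qualified", "withdrawn_behaviour"}
    if extra:
        raise ScaleError(
            f"item screen expects a qualified/withdrawn_behaviour cohort, got {sorted(extra)}"
        )
    outcome = cohort.outcome_of()
    rows = []
    for age in AGE_POINTS:
        wide = cohort.wide_responses(age)
        y_all = (outcome.reindex(wide.index) == "withdrawn_behaviour").astype(float)
        for item in items:
            if item not in wide.columns:
                rows.append((item, age, float("nan"), "absent"))
                continue
            sub = pd.DataFrame({"x": wide[item], "y": y_all}).dropna()
            if len(sub) < 10 or sub["y"].nunique() < 2:
                rows.append((item, age, float("nan"), "degenerate"))
                continue
            p, status = _univariate_logit_p(sub["x"].to_numpy(), sub["y"].to_numpy())
            rows.append((item, age, p, status))
    table = pd.DataFrame(rows, columns=["item_id", "age_point", "p", "status"])
    sig = table[(table["status"] == "separated") | (table["p"] < alpha)]
    retained = [i for i in items if i in set(sig["item_id"])]
    return retained, table


def _name_group(items: list[str], taken: set[str]) -> str:
    """Name a scale after the trait most of its items were designed for."""
    designed = [ITEM_TRAIT.get(i) for i in items if ITEM_TRAIT.get(i)]
    name = Counter(designed).most_common(1)[0][0] if designed else "Scale"
    base, n = name, 2
    while name in taken:
        name = f"{base} {n}"
        n += 1
    return name


def accept_scales(
    groupings: list[tuple[list[str], str]],
    data_by_age: dict[str, pd.DataFrame],
    floor: float = 0.70,
    reference_age: str = "12M",
) -> list[ScaleDefinition]:
    """Accept a grouping as a scale iff its direction-corrected alpha
    exceeds ``floor`` at every age; alphas are recorded per age.

    ``groupings`` pairs each item list with its provenance ("pca" or
    "alpha_refinement").  Directions are detected on the reference age.
    """
    scales: list[ScaleDefinition] = []
    taken: set[str] = set()
    for items, provenance in groupings:
        if len(items) < 2:
            continue
        direction = detect_reverse_items(items, data_by_age[reference_age])
        alphas = {}
        ok = True
        for age, wide in data_by_age.items():
            mat = wide[items].copy()
            for item in items:
                if direction[item] == "-":
                    mat[item] = 100.0 - mat[item]
            try:
                a = cronbach_alpha(mat)
            except ScaleError:
                ok = False
                break
            alphas[age] = a
            if a <= floor:
                ok = False
        if ok:
            name = _name_group(items, taken)
            taken.add(name)
            scales.append(
                ScaleDefinition(name, list(items), direction, alphas, provenance)
            )
    return scales


def _stable_groupings(groups_by_age: dict[str, list[list[str]]]) -> tuple[list[list[str]], set[str]]:
    """Item groupings that are consistent across ages.

    Two items "co-load" if they fall in the same rotated component in at
    least two of the per-age solutions; the connected components of this
    co-loading relation (with >= 2 items) are the stable groupings.
    This is robust to a single item drifting in or out of a large
    component at one age, which an exact item-set match is not.
    """
    pair_count: Counter = Counter()
    for groups in groups_by_age.values():
        for g in groups:
            g = sorted(g)
            for i in range(len(g)):
                for j in range(i + 1, len(g)):
                    pair_count[(g[i], g[j])] += 1
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), c in pair_count.items():
        if c >= 2:
            parent[find(a)] = find(b)
    clusters: dict[str, list[str]] = {}
    for x in parent:
        clusters.setdefault(find(x), []).append(x)
    stable = [sorted(g) for g in clusters.values() if len(g) >= 2]
    consistent = set().union(*map(set, stable)) if stable else set()
    return stable, consistent


def build_scales(
    cohort: Cohort,
    items: list[str],
    salience: float = 0.40,
    gain_threshold: float = 0.05,
    alpha_floor: float = 0.70,
    screen: bool = True,
    screen_alpha: float = 0.05,
    reference_age: str = "12M",
) -> tuple[list[ScaleDefinition], pd.DataFrame | None]:
    """Run the full scale-construction stage on a development cohort.

    PCA at each age; item sets that recur at >= 2 ages are kept as
    stable groupings (provenance "pca"); all remaining items are pooled
    and re-grouped by greedy alpha refinement on the reference-age data
    (provenance "alpha_refinement"); groupings are accepted as scales if
    alpha > ``alpha_floor`` at all three ages; finally the predictive
    item screen removes items with no association with outcome at any
    age.  Returns (scales, screening table or None).
    """
    data_by_age = {
        age: cohort.wide_responses(age).reindex(columns=items) for age in AGE_POINTS
    }
    groups_by_age = {
        age: pca_group(wide.dropna(axis=1, how="all"), salience)[1]
        for age, wide in data_by_age.items()
    }
    stable, consistent = _stable_groupings(groups_by_age)
    groupings: list[tuple[list[str], str]] = [(g, "pca") for g in stable]
    leftover = [i for i in items if i not in consistent]
    if len(leftover) >= 2:
        refined, _ = alpha_refine(
            data_by_age[reference_age][leftover],
            gain_threshold=gain_threshold,
            candidate_floor=alpha_floor,
        )
        groupings += [(g, "alpha_refinement") for g in refined]
    scales = accept_scales(groupings, data_by_age, alpha_floor, reference_age)

    screen_table = None
    if screen and scales:
        scale_items = [i for s in scales for i in s.items]
        dev = filter_by_outcome(cohort, {"qualified", "withdrawn_behaviour"})
        retained, screen_table = item_screen(dev, scale_items, screen_alpha)
        kept: list[ScaleDefinition] = []
        for s in scales:
            items_kept = [i for i in s.items if i in retained]
            if len(items_kept) >= 2:
                kept.append(
                    ScaleDefinition(
                        s.name,
                        items_kept,
                        {i: s.direction[i] for i in items_kept},
                        s.alpha_by_age,
                        s.provenance,
                    )
                )
        scales = kept
    return scales, screen_table
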