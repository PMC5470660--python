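from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pupscales.core_data import Cohort
from pupscales.items import ALL_ITEMS, ITEM_SIGN, SCALE_ITEMS
from pupscales.scales import (
    ScaleDefinition,
    ScaleError,
    accept_scales,
    alpha_refine,
    cronbach_alpha,
    detect_reverse_items,
    item_screen,
    pca_group,
    scale_scores,
)
from pupscales.synthetic import GeneratorConfig, generate_cohort


def naive_varimax(L, iterations=500):
    """Independent pairwise-Jacobi varimax (Kaiser-normalised oracle)."""
    L = np.asarray(L, float).copy()
    comm = np.sqrt((L**2).sum(1))
    comm[comm == 0] = 1
    L /= comm[:, None]
    p, k = L.shape
    for _ in range(iterations):
        changed = 0.0
        for i in range(k):
            for j in range(i + 1, k):
                x, y = L[:, i], L[:, j]
                u, v = x**2 - y**2, 2 * x * y
                num = 2 * (p * (u * v).sum() - u.sum() * v.sum())
                den = p * (u**2 - v**2).sum() - (u.sum() ** 2 - v.sum() ** 2)
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-10:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                L[:, i], L[:, j] = c * x + s * y, -s * x + c * y
                changed += abs(phi)
        if changed < 1e-9:
            break
    return L * comm[:, None]


def two_block_data(n=400, seed=0, r_extra=0.0):
    rng = np.random.default_rng(seed)
    fa, fb = rng.standard_normal(n), rng.standard_normal(n)
    fb = r_extra * fa + np.sqrt(1 - r_extra**2) * fb
    cols = {}
    for i in range(3):
        cols[f"a{i}"] = 50 + 14 * fa + rng.normal(0, 7, n)
        cols[f"b{i}"] = 50 + 14 * fb + rng.normal(0, 7, n)
    return pd.DataFrame(cols).clip(0, 100).round()


class TestCronbachAlpha:
    def test_hand_fixture_matches_variance_formula(self):
        X = pd.DataFrame(
            [
                [10, 12, 8, 11],
                [20, 18, 22, 19],
                [35, 33, 30, 36],
                [50, 52, 55, 49],
                [65, 60, 66, 63],
                [80, 84, 78, 82],
            ],
            dtype=float,
        )
        # hand computation: item variances sum 2931.667, total-score var 11646.4
        assert cronbach_alpha(X) == pytest.approx(0.9977026758864922, abs=1e-12)
        assert cronbach_alpha(X) == pytest.approx(pg.cronbach_alpha(X)[0], abs=1e-12)

    def test_identical_items_give_one(self):
        x = pd.Series([1.0, 5, 9, 2, 7])
        assert cronbach_alpha(pd.DataFrame({"a": x, "b": x})) == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(5000, 2)), columns=["a", "b"])
        assert abs(cronbach_alpha(X)) < 0.1

    def test_zero_total_variance_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3], "b": [3.0, 2, 1]})
        with pytest.raises(ScaleError, match="variance"):
            cronbach_alpha(X)

    def test_agrees_with_pingouin_on_random_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            X = pd.DataFrame(rng.normal(50, 15, size=(40, 5)))
            assert cronbach_alpha(X) == pytest.approx(
                pg.cronbach_alpha(X)[0], abs=1e-10
            )


class TestPcaGroup:
    def test_two_independent_blocks_recovered(self):
        sol, groups = pca_group(two_block_data())
        assert sol.n_retained == 2
        sets = {frozenset(g) for g in groups}
        assert sets == {frozenset({"a0", "a1", "a2"}), frozenset({"b0", "b1", "b2"})}

    def test_eigenvalues_match_char_poly_oracle(self):
        data = two_block_data(seed=3)
        sol, _ = pca_group(data)
        R = np.corrcoef(data.to_numpy(), rowvar=False)
        oracle = np.sort(np.real(np.roots(np.poly(R))))[::-1]
        np.testing.assert_allclose(sol.eigenvalues, oracle, atol=1e-6)

    def test_loadings_match_naive_varimax_oracle(self):
        data = two_block_data(seed=5)
        sol, _ = pca_group(data)
        R = np.corrcoef(data.to_numpy(), rowvar=False)
        evals, evecs = np.linalg.eigh(R)
        order = np.argsort(evals)[::-1]
        raw = evecs[:, order[:2]] * np.sqrt(evals[order[:2]])
        oracle = naive_varimax(raw)
        got = sol.loadings.to_numpy()
        # match up to column order and sign
        for j in range(2):
            matched = False
            for jo in range(2):
                for sign in (1, -1):
                    if np.allclose(got[:, j], sign * oracle[:, jo], atol=1e-6):
                        matched = True
            assert matched

    def test_rotation_cross_checked_against_r_varimax(self, tmp_path):
        """R's stats::varimax agrees on grouping; our rotation achieves
        at least as high a varimax criterion (R stops earlier)."""
        import subprocess

        from pupscales.scales import varimax

        data = two_block_data(seed=5)
        R = np.corrcoef(data.to_numpy(), rowvar=False)
        evals, evecs = np.linalg.eigh(R)
        order = np.argsort(evals)[::-1]
        raw = evecs[:, order[:2]] * np.sqrt(evals[order[:2]])
        np.savetxt(tmp_path / "raw.txt", raw)
        script = tmp_path / "vm.R"
        script.write_text(
            f"L <- as.matrix(read.table('{tmp_path}/raw.txt'))\n"
            "v <- varimax(L, normalize=TRUE, eps=1e-9)\n"
            f"write.table(unclass(v$loadings), '{tmp_path}/rot.txt', "
            "row.names=FALSE, col.names=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        r_rot = np.loadtxt(tmp_path / "rot.txt")
        mine, _ = varimax(raw)

        def criterion(L):
            comm = np.sqrt((raw**2).sum(1))
            return ((L / comm[:, None]) ** 2).var(axis=0).sum()

        assert criterion(mine) >= criterion(r_rot) - 1e-9
        np.testing.assert_array_equal(
            np.abs(mine).argmax(1), np.abs(r_rot).argmax(1)
        )

    def test_null_structure_eigenvalues_near_one_and_unstable(self):
        rng = np.random.default_rng(1)
        data1 = pd.DataFrame(rng.normal(50, 10, size=(5000, 5)))
        data2 = pd.DataFrame(rng.normal(50, 10, size=(5000, 5)))
        sol1, groups1 = pca_group(data1)
        sol2, groups2 = pca_group(data2)
        assert np.all(np.abs(sol1.eigenvalues - 1) < 0.2)
        # any apparent grouping is noise: it does not replicate
        assert {frozenset(g) for g in groups1} != {frozenset(g) for g in groups2}

    def test_cross_loading_item_kept_on_stronger_component(self):
        rng = np.random.default_rng(8)
        n = 2000
        fa, fb = rng.standard_normal(n), rng.standard_normal(n)
        cols = {f"a{i}": 50 + 14 * fa + rng.normal(0, 6, n) for i in range(3)}
        cols |= {f"b{i}": 50 + 14 * fb + rng.normal(0, 6, n) for i in range(3)}
        # cross item: loads ~0.6 on A and ~0.45 on B
        cols["x"] = 50 + 9.5 * fa + 7.0 * fb + rng.normal(0, 7, n)
        sol, groups = pca_group(pd.DataFrame(cols))
        a_grp = next(g for g in groups if "a0" in g)
        b_grp = next(g for g in groups if "b0" in g)
        assert abs(sol.loadings.loc["x"]).max() >= 0.40
        assert "x" in a_grp and "x" not in b_grp

    def test_collinear_items_rejected(self):
        x = pd.Series(np.arange(10, dtype=float))
        data = pd.DataFrame({"a": x, "b": x, "c": x[::-1].to_numpy() + 1})
        with pytest.raises(ScaleError, match="collinear"):
            pca_group(data)

    def test_too_few_complete_dogs_rejected(self):
        data = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 5)))
        with pytest.raises(ScaleError, match="complete dogs"):
            pca_group(data)


def refine_fixture():
    rng = np.random.default_rng(42)
    n = 120
    f = rng.normal(0, 1, n)
    items = {
        f"g{i}": np.clip(np.round(50 + 14 * f + rng.normal(0, 9, n)), 0, 100)
        for i in range(5)
    }
    items["bad"] = np.clip(np.round(50 - 4 * f + rng.normal(0, 18, n)), 0, 100)
    return pd.DataFrame(items)


class TestAlphaRefine:
    def test_anticorrelated_item_pooled_out(self):
        df = refine_fixture()
        groups, leftover = alpha_refine(df)
        assert groups == [["g0", "g1", "g2", "g3", "g4"]]
        assert leftover == ["bad"]

    def test_matches_exhaustive_subset_search(self):
        df = refine_fixture()

        def alpha_of(cols):
            return cronbach_alpha(df[list(cols)])

        best = max(
            (c for r in range(2, 7) for c in combinations(df.columns, r)),
            key=alpha_of,
        )
        groups, _ = alpha_refine(df)
        assert set(groups[0]) == set(best)

    def test_reliable_pool_is_fixed_point(self):
        df = refine_fixture()[["g0", "g1", "g2", "g3", "g4"]]
        groups, leftover = alpha_refine(df)
        assert groups == [["g0", "g1", "g2", "g3", "g4"]]
        assert leftover == []

    def test_unreliable_pair_forms_no_grouping(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(50, 10, size=(200, 2)), columns=["a", "b"])
        groups, leftover = alpha_refine(df)
        assert groups == []
        assert set(leftover) == {"a", "b"}

    def test_refined_alpha_not_below_pool_alpha(self):
        df = refine_fixture()
        from pupscales.scales import orient_items

        pool_alpha = cronbach_alpha(orient_items(df))
        groups, _ = alpha_refine(df)
        assert cronbach_alpha(df[groups[0]]) >= pool_alpha


class TestAcceptScales:
    def _ages(self, alphas, seed=0):
        """3-item groups whose per-age alpha is tuned via noise level."""
        rng = np.random.default_rng(seed)
        n = 500
        data = {}
        for age, target in zip(("5M", "8M", "12M"), alphas):
            r = target / (3 - 2 * target)
            c = np.sqrt(r)
            lam = 10 * c / np.sqrt(1 - c * c)
            f = rng.standard_normal(n)
            data[age] = pd.DataFrame(
                {
                    f"i{k}": np.clip(50 + lam * f + rng.normal(0, 10, n), 0, 100)
                    for k in range(3)
                }
            )
        return data

    def test_reliable_grouping_accepted_with_alphas_recorded(self):
        data = self._ages((0.82, 0.87, 0.88))
        scales = accept_scales([(["i0", "i1", "i2"], "pca")], data, 0.70)
        assert len(scales) == 1
        assert set(scales[0].alpha_by_age) == {"5M", "8M", "12M"}
        assert all(a > 0.70 for a in scales[0].alpha_by_age.values())

    def test_single_weak_age_rejects(self):
        data = self._ages((0.80, 0.55, 0.80))
        assert accept_scales([(["i0", "i1", "i2"], "pca")], data, 0.70) == []

    def test_empty_groupings_give_empty_scales(self):
        assert accept_scales([], {}, 0.70) == []


class TestDetectReverseItems:
    def test_all_positive_items_unreversed(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal(300)
        df = pd.DataFrame(
            {f"i{k}": 50 + 12 * f + rng.normal(0, 8, 300) for k in range(4)}
        )
        assert set(detect_reverse_items(list(df), df).values()) == {"+"}

    def test_generator_keying_recovered(self):
        cohort, _ = generate_cohort(GeneratorConfig(n_dogs=500, seed=3))
        wide = cohort.wide_responses("12M")
        items = SCALE_ITEMS["Trainability"]
        direction = detect_reverse_items(items, wide)
        expected = {i: ("+" if ITEM_SIGN[i] > 0 else "-") for i in items}
        assert direction == expected

    def test_exact_zero_correlation_stays_positive(self):
        v = np.array([10.0, 20, 30, 40])
        x = np.array([30.0, 10, 10, 30])  # exactly orthogonal to v
        df = pd.DataFrame({"a": v, "b": v, "c": x})
        assert np.corrcoef(x, v)[0, 1] == pytest.approx(0.0, abs=1e-15)
        assert detect_reverse_items(["a", "b", "c"], df)["c"] == "+"

    def test_zero_variance_item_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.raises(ScaleError, match="zero-variance"):
            detect_reverse_items(["a", "b"], df)


class TestScaleScore:
    def _scale(self, directions):
        return ScaleDefinition(
            "S", list(directions), {k: v for k, v in directions.items()}
        )

    def test_reverse_coding_hand_example(self):
        scale = self._scale({"p": "+", "q": "-"})
        wide = pd.DataFrame({"p": [80.0], "q": [30.0]}, index=["d1"])
        assert scale_scores(scale, wide).loc["d1"] == pytest.approx(75.0)

    def test_all_missing_gives_missing(self):
        scale = self._scale({"p": "+", "q": "-"})
        wide = pd.DataFrame({"p": [np.nan], "q": [np.nan]}, index=["d1"])
        assert np.isnan(scale_scores(scale, wide).loc["d1"])

    def test_half_answered_rule(self):
        scale = ScaleDefinition(
            "S", ["a", "b", "c", "d"], {i: "+" for i in "abcd"}
        )
        wide = pd.DataFrame(
            {"a": [60.0, 60.0], "b": [80.0, np.nan], "c": [np.nan] * 2, "d": [np.nan] * 2},
            index=["two", "one"],
        )
        out = scale_scores(scale, wide)
        assert out.loc["two"] == pytest.approx(70.0)  # 2 of 4 answered: kept
        assert np.isnan(out.loc["one"])  # 1 of 4: missing

    @settings(max_examples=30, deadline=None)
    @given(
        arrays(
            float,
            (6, 4),
            elements=st.floats(min_value=0, max_value=100, allow_nan=False),
        )
    )
    def test_bounded_and_item_order_invariant(self, mat):
        items = ["a", "b", "c", "d"]
        scale = ScaleDefinition("S", items, {"a": "+", "b": "-", "c": "+", "d": "-"})
        wide = pd.DataFrame(mat, columns=items)
        s1 = scale_scores(scale, wide)
        assert s1.dropna().between(0, 100).all()
        shuffled = ScaleDefinition(
            "S", items[::-1], {"a": "+", "b": "-", "c": "+", "d": "-"}
        )
        s2 = scale_scores(shuffled, wide[items[::-1]])
        pd.testing.assert_series_equal(s1, s2)


class TestItemScreen:
    def _cohort(self, n=400, seed=0, effect=0.08):
        rng = np.random.default_rng(seed)
        x_strong = rng.normal(50, 15, n)
        x_null = rng.normal(50, 15, n)
        p = 1 / (1 + np.exp(-(-4.0 + effect * x_strong)))
        y = rng.uniform(size=n) < p
        dogs = pd.DataFrame(
            {
                "dog_id": [f"d{i}" for i in range(n)],
                "breed": "Lab",
                "sex": "M",
                "birth_date": pd.Timestamp("2012-01-01"),
                "training_entry_date": pd.Timestamp("2013-03-01"),
                "outcome": np.where(y, "withdrawn_behaviour", "qualified"),
                "outcome_date": pd.Timestamp("2013-10-01"),
            }
        )
        resp = pd.concat(
            [
                pd.DataFrame(
                    {
                        "dog_id": dogs.dog_id,
                        "age_point": "5M",
                        "item_id": name,
                        "value": np.clip(np.round(v), 0, 100),
                    }
                )
                for name, v in (("strong", x_strong), ("null", x_null))
            ],
            ignore_index=True,
        )
        return Cohort(dogs=dogs, responses=resp)

    def test_strong_item_retained_null_often_removed(self):
        cohort = self._cohort()
        retained, table = item_screen(cohort, ["strong", "null"])
        assert "strong" in retained
        p_null = table.loc[table.item_id == "null", "p"].iloc[0]
        assert p_null > 0.05  # this seed: no spurious signal

    def test_constant_item_removed(self):
        cohort = self._cohort()
        flat = cohort.responses.copy()
        flat.loc[flat.item_id == "null", "value"] = 50.0
        cohort2 = Cohort(dogs=cohort.dogs, responses=flat)
        retained, table = item_screen(cohort2, ["strong", "null"])
        assert "null" not in retained
        assert (table.loc[table.item_id == "null", "status"] == "no_variance").any()

    def test_perfect_separation_counts_as_significant(self):
        cohort = self._cohort(n=60, seed=1)
        sep = cohort.responses.copy()
        y = cohort.outcome_of()
        sep.loc[sep.item_id == "null", "value"] = [
            90.0 if y[d] == "withdrawn_behaviour" else 10.0
            for d in sep.loc[sep.item_id == "null", "dog_id"]
        ]
        cohort2 = Cohort(dogs=cohort.dogs, responses=sep)
        retained, table = item_screen(cohort2, ["null"])
        assert "null" in retained
        assert (table.loc[table.item_id == "null", "status"] == "separated").any()

    def test_mixed_outcome_cohort_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ScaleError, match="qualified/withdrawn_behaviour"):
            item_screen(cohort, list(ALL_ITEMS)[:2])
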