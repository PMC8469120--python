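"""Growth statistics: series assembly, Pearson, ANOVA/Tukey, lm, germination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenocanopy import (
    BiomassRecord,
    ExperimentLayout,
    GrowthSeries,
    PotRoi,
    anova_tukey,
    build_series,
    call_germination,
    germination_fractions,
    growth_summary,
    pearson_correlation,
    treatment_lm,
)


def tiny_layout():
    pots = [
        PotRoi("p1", "rectangle", (0, 0, 10, 10), treatment="control", replicate=1),
        PotRoi("p2", "rectangle", (10, 0, 20, 10), treatment="drought", replicate=1),
    ]
    return ExperimentLayout(name="t", pots=pots)


class TestBuildSeries:
    def test_shuffled_days_sorted_ascending(self):
        recs = [
            BiomassRecord("p1", 9, 300, 0),
            BiomassRecord("p1", 3, 50, 0),
            BiomassRecord("p1", 7, 200, 10),
        ]
        (s,) = build_series(recs, tiny_layout())
        assert list(s.days) == [3, 7, 9]
        assert list(s.green_pixels) == [50, 200, 300]
        assert s.treatment == "control"

    def test_duplicate_pot_day_rejected(self):
        recs = [BiomassRecord("p1", 3, 10, 0), BiomassRecord("p1", 3, 20, 0)]
        with pytest.raises(ValueError, match="duplicate"):
            build_series(recs, tiny_layout())

    def test_unknown_pot_ids_listed(self):
        recs = [BiomassRecord("ghost", 3, 10, 0), BiomassRecord("zombie", 4, 5, 0)]
        with pytest.raises(ValueError, match="ghost.*zombie"):
            build_series(recs, tiny_layout())

    def test_empty_records_give_empty_output(self):
        assert build_series([], tiny_layout()) == []


class TestPearson:
    def test_perfect_positive_line(self):
        x = np.arange(1, 8.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_perfect_negative_line(self):
        x = np.arange(1, 6.0)
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_matches_from_scratch_formula(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 2, 3, 5])
        res = pearson_correlation(x, y)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        want = cov / (x.std() * y.std())
        assert res.r == pytest.approx(want, abs=1e-12)
        # two-sided t transform with n - 2 df
        t = want * np.sqrt(2 / (1 - want**2))
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), 2), abs=1e-12)

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(0)
        x = rng.random(30)
        y = rng.random(30)
        base = pearson_correlation(x, y).r
        assert pearson_correlation(3 * x + 2, y).r == pytest.approx(base, abs=1e-12)
        assert pearson_correlation(-2 * x + 1, y).r == pytest.approx(-base, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [1, 2])
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestAnovaTukey:
    def test_two_groups_reduce_to_pooled_t_test(self):
        rng = np.random.default_rng(1)
        a = rng.normal(10, 2, 8)
        b = rng.normal(12, 2, 9)
        res = anova_tukey({"a": a.tolist(), "b": b.tolist()})
        t_p = stats.ttest_ind(a, b).pvalue
        assert len(res.comparisons) == 1
        assert res.comparisons[0].p_adj == pytest.approx(t_p, abs=1e-8)
        assert res.p_value == pytest.approx(t_p, abs=1e-8)

    def test_three_groups_match_independent_implementation(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(mu, 1.5, 7).tolist() for k, mu in [("a", 5), ("b", 6), ("c", 8)]}
        res = anova_tukey(groups)
        f, p = stats.f_oneway(*groups.values())
        assert res.f_stat == pytest.approx(f, abs=1e-10)
        oracle = stats.tukey_hsd(*groups.values())
        names = list(groups)
        for comp in res.comparisons:
            i, j = names.index(comp.group_a), names.index(comp.group_b)
            assert comp.p_adj == pytest.approx(oracle.pvalue[i, j], abs=1e-8)
            assert comp.mean_diff == pytest.approx(
                np.mean(groups[comp.group_b]) - np.mean(groups[comp.group_a]), abs=1e-10
            )

    def test_identical_constant_groups_error_and_near_null_high_p(self):
        with pytest.raises(ValueError, match="variance"):
            anova_tukey({"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        near = {
            "a": [5.0, 5.0001, 4.9999, 5.0],
            "b": [5.0001, 5.0, 5.0, 4.9999],
            "c": [5.0, 4.9999, 5.0001, 5.0],
        }
        res = anova_tukey(near)
        assert all(c.p_adj > 0.9 for c in res.comparisons)

    def test_tukey_never_more_significant_than_raw_t(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(5 + i, 1, 6).tolist() for i, k in enumerate("abcd")}
        res = anova_tukey(groups)
        for comp in res.comparisons:
            raw = stats.ttest_ind(groups[comp.group_a], groups[comp.group_b]).pvalue
            assert comp.p_adj >= raw - 1e-12

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="n=1"):
            anova_tukey({"a": [1.0], "b": [1.0, 2.0]})

    def test_null_type_one_error_calibrated(self):
        # with no true effect, rejection rate at alpha=0.05 stays near 0.05
        rng = np.random.default_rng(2024)
        n_sims, alpha = 2000, 0.05
        rejections = 0
        for _ in range(n_sims):
            groups = [rng.normal(0, 1, 6) for _ in range(4)]
            _, p = stats.f_oneway(*groups)
            rejections += p < alpha
        assert rejections / n_sims == pytest.approx(alpha, abs=0.02)


class TestTreatmentLm:
    def test_equal_means_give_zero_slope(self):
        vals = [("ctl", 5.0), ("ctl", 7.0), ("trt", 5.0), ("trt", 7.0)]
        table = treatment_lm(vals, reference="ctl")
        slope = table[table["term"] == "trt"].iloc[0]
        assert slope["estimate"] == pytest.approx(0.0, abs=1e-12)
        assert slope["p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_intercept_is_reference_mean(self):
        rng = np.random.default_rng(4)
        vals = [("A", v) for v in rng.normal(10, 1, 5)] + [
            ("B", v) for v in rng.normal(12, 1, 6)
        ] + [("C", v) for v in rng.normal(9, 1, 4)]
        table = treatment_lm(vals, reference="A")
        ref_mean = np.mean([v for t, v in vals if t == "A"])
        assert table.iloc[0]["estimate"] == pytest.approx(ref_mean, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        treatments = ["A"] * 6 + ["B"] * 5 + ["C"] * 7
        y = rng.normal(0, 1, len(treatments))
        vals = list(zip(treatments, y))
        table = treatment_lm(vals, reference="A")
        X = np.column_stack(
            [
                np.ones(len(y)),
                [1.0 if t == "B" else 0.0 for t in treatments],
                [1.0 if t == "C" else 0.0 for t in treatments],
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(table["estimate"].to_numpy(), beta, atol=1e-10)
        resid = y - X @ beta
        s2 = resid @ resid / (len(y) - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(table["std_err"].to_numpy(), se, atol=1e-10)
        t_stats = beta / se
        p = 2 * stats.t.sf(np.abs(t_stats), len(y) - 3)
        np.testing.assert_allclose(table["p_value"].to_numpy(), p, atol=1e-8)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            treatment_lm([("A", 1.0), ("B", 2.0)], reference="Z")


def make_series(pot_id, treatment, days, greens, rep=1):
    return GrowthSeries(
        pot_id=pot_id,
        treatment=treatment,
        replicate=rep,
        days=np.array(days),
        green_pixels=np.array(greens),
        yellow_pixels=np.zeros(len(days), int),
    )


class TestGermination:
    def test_first_crossing_day(self):
        s = make_series("u1", "A", [1, 3, 5], [0, 10, 200])
        assert call_germination(s, min_area_px=50).day_of_emergence == 5

    def test_never_crossing_gives_none(self):
        s = make_series("u1", "A", [1, 3, 5], [0, 0, 0])
        assert call_germination(s, min_area_px=50).day_of_emergence is None

    def test_fractions_nondecreasing_and_match_schedule(self):
        series = [
            make_series("a1", "A", [1, 3, 5, 7], [0, 60, 100, 200]),
            make_series("a2", "A", [1, 3, 5, 7], [0, 0, 80, 150]),
            make_series("b1", "B", [1, 3, 5, 7], [70, 90, 120, 300]),
            make_series("b2", "B", [1, 3, 5, 7], [0, 0, 0, 0]),
        ]
        table = germination_fractions(series, min_area_px=50)
        a = table[table["treatment"] == "A"].sort_values("day")["fraction"].tolist()
        b = table[table["treatment"] == "B"].sort_values("day")["fraction"].tolist()
        assert a == [0.0, 0.5, 1.0, 1.0]
        assert b == [0.5, 0.5, 0.5, 0.5]
        for frac in (a, b):
            assert all(x <= y for x, y in zip(frac, frac[1:]))


class TestGrowthSummary:
    def test_single_replicate_se_missing(self):
        table = growth_summary([make_series("u1", "A", [1, 3], [10, 20])])
        assert table["n"].tolist() == [1, 1]
        assert table["se"].isna().all()

    def test_identical_replicates_zero_se(self):
        series = [
            make_series("u1", "A", [1, 3], [10, 20]),
            make_series("u2", "A", [1, 3], [10, 20], rep=2),
        ]
        table = growth_summary(series)
        assert (table["se"] == 0).all()
        assert (table["mean"] == [10, 20]).all()

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        greens = rng.integers(0, 1000, (4, 3))
        series = [
            make_series(f"u{i}", "A", [2, 4, 6], greens[i], rep=i + 1) for i in range(4)
        ]
        table = growth_summary(series).sort_values("day")
        for j, day in enumerate([2, 4, 6]):
            row = table[table["day"] == day].iloc[0]
            col = greens[:, j]
            assert row["mean"] == pytest.approx(col.mean())
            assert row["se"] == pytest.approx(col.std(ddof=1) / 2.0)

    def test_series_invariants_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_series("u", "A", [3, 3, 5], [1, 2, 3])
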