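"""Stage-stratified statistics: ANOVA, contrasts, permutation p, Fisher tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bindgap import exprstats
from bindgap.exprstats import (
    DegenerateDataError,
    ExpressionDataset,
    TwoByTwoTable,
    anova_from_arrays,
    log_transform,
    one_way_anova,
    permutation_f_from_arrays,
    permutation_f_test,
    proportion_test,
    run_group_analysis,
    stage_contrast,
)
from conftest import make_dataset


class TestLogTransform:
    def test_values_and_flag(self):
        ds = make_dataset({"a": [0, 7], "b": [1, 3]}, transform="none")
        out = log_transform(ds, pseudocount=1.0)
        assert out.transform == "log2"
        np.testing.assert_allclose(out.values.loc["G"].to_numpy()[:2], [0.0, 3.0])

    def test_monotone(self):
        ds = make_dataset({"a": [0.5, 2.0, 9.0, 100.0]}, transform="none")
        out = log_transform(ds).values.loc["G"].to_numpy()
        assert (np.diff(out) > 0).all()

    def test_retransform_rejected(self):
        ds = make_dataset({"a": [1, 2]}, transform="none")
        with pytest.raises(ValueError, match="already transformed"):
            log_transform(log_transform(ds))


class TestOneWayAnova:
    def test_identical_groups_give_zero_f(self):
        ds = make_dataset({"a": [1, 2, 3], "b": [1, 2, 3]})
        res = one_way_anova(ds, "G")
        assert res.f == 0.0
        assert res.p == 1.0

    def test_hand_oracle(self, toy_dataset):
        # SSB = 16, SSW = 1.5, df (2, 3) -> F = (16/2)/(1.5/3) = 16
        res = one_way_anova(toy_dataset, "G")
        assert res.f == pytest.approx(16.0)
        assert (res.df_between, res.df_within) == (2, 3)

    def test_location_invariance(self, toy_dataset):
        base = one_way_anova(toy_dataset, "G")
        shifted = ExpressionDataset(
            toy_dataset.values + 100.0, toy_dataset.sample_meta, transform="log2"
        )
        assert one_way_anova(shifted, "G").f == pytest.approx(base.f)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=30)
        codes = np.repeat([0, 1, 2], 10)
        res = anova_from_arrays(y, codes)
        f_ref, p_ref = stats.f_oneway(y[:10], y[10:20], y[20:])
        assert res.f == pytest.approx(f_ref)
        assert res.p == pytest.approx(p_ref)

    def test_degenerate_and_single_level_errors(self):
        with pytest.raises(DegenerateDataError):
            anova_from_arrays(np.array([5.0, 5.0, 5.0, 5.0]), np.array([0, 0, 1, 1]))
        with pytest.raises(ValueError, match="2 factor levels"):
            anova_from_arrays(np.array([1.0, 2.0]), np.array([0, 0]))


class TestStageContrast:
    def test_null_contrast(self):
        ds = make_dataset({"a": [1, 2, 3], "b": [1, 2, 3], "c": [9, 10, 11]})
        res = stage_contrast(ds, "G", {"a": -1, "b": 1})
        assert res.estimate == 0.0
        assert res.p == 1.0

    def test_hand_oracle(self, toy_dataset):
        # means (1.5, 3.5, 5.5), MSE = 0.5 -> estimate 4, SE = sqrt(0.5) -> t = 5.657
        res = stage_contrast(toy_dataset, "G", {"a": -1, "c": 1})
        assert res.estimate == pytest.approx(4.0)
        assert res.t == pytest.approx(5.657, abs=1e-3)
        assert res.df == 3

    def test_two_level_equals_pooled_t(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        ds = make_dataset({"x": a, "y": b})
        res = stage_contrast(ds, "G", {"x": -1, "y": 1})
        t_ref, p_ref = stats.ttest_ind(b, a, equal_var=True)
        assert res.t == pytest.approx(t_ref)
        assert res.p == pytest.approx(p_ref)

    def test_invalid_weights(self, toy_dataset):
        with pytest.raises(ValueError, match="sum to 0"):
            stage_contrast(toy_dataset, "G", {"a": 1, "c": 1})
        with pytest.raises(ValueError, match="absent"):
            stage_contrast(toy_dataset, "G", {"a": -1, "nope": 1})


def exact_permutation_p(y, codes):
    """Exhaustive Pr(F > f_obs) over all distinct label assignments."""
    f_obs = anova_from_arrays(y, codes).f
    n = len(y)
    exceed = total = 0
    for perm in set(itertools.permutations(codes)):
        total += 1
        if anova_from_arrays(y, np.array(perm)).f > f_obs:
            exceed += 1
    return exceed / total


class TestPermutationTest:
    def test_determinism(self, toy_dataset):
        a = permutation_f_test(toy_dataset, "G", n_perm=200, seed=5)
        b = permutation_f_test(toy_dataset, "G", n_perm=200, seed=5)
        assert a == b

    def test_exhaustive_oracle_two_levels(self):
        # 6 samples, 2 levels of 3: 20 distinct assignments enumerated exactly
        y = np.array([1.2, 0.7, 2.9, 1.4, 3.3, 2.1])
        codes = np.array([0, 0, 0, 1, 1, 1])
        exact = exact_permutation_p(y, codes)
        sampled = permutation_f_from_arrays(y, codes, n_perm=40000, seed=9).p_empirical
        assert sampled == pytest.approx(exact, abs=0.01)

    def test_overwhelming_effect_gives_zero(self):
        rng = np.random.default_rng(13)
        ds = make_dataset({"a": rng.normal(0, 1, 10), "b": rng.normal(100, 1, 10)})
        res = permutation_f_test(ds, "G", n_perm=1000, seed=1)
        assert res.p_empirical == 0.0

    def test_relabel_invariance(self):
        y = np.arange(12, dtype=float) ** 1.3
        codes = np.array([0, 1, 2] * 4)
        p1 = permutation_f_from_arrays(y, codes, n_perm=500, seed=3).p_empirical
        relabeled = np.array([2, 0, 1])[codes]  # rename the levels
        p2 = permutation_f_from_arrays(y, relabeled, n_perm=500, seed=3).p_empirical
        assert p1 == p2

    def test_p_is_multiple_of_inverse_nperm(self, toy_dataset):
        res = permutation_f_test(toy_dataset, "G", n_perm=250, seed=2)
        assert (res.p_empirical * 250) == pytest.approx(round(res.p_empirical * 250))

    def test_smoothed_estimator_strictly_positive(self, toy_dataset):
        res = permutation_f_test(toy_dataset, "G", n_perm=100, seed=2, smoothed=True)
        assert 0.0 < res.p_empirical <= 1.0


def exact_fisher_two_sided(a, b, c, d):
    """Brute-force two-sided Fisher p: sum point probabilities <= observed."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        px = stats.hypergeom.pmf(x, n, col1, row1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestProportionTest:
    def test_printed_mutation_counts(self):
        # 2/77 vs 12/172 mutant/wild-type: OR = 320/900, not significant
        res = proportion_test(TwoByTwoTable(2, 75, 12, 160))
        assert res.odds_ratio == pytest.approx(320 / 900)
        assert res.p > 0.05

    def test_identical_rows(self):
        res = proportion_test(TwoByTwoTable(5, 9, 5, 9))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [(1, 9, 9, 1), (3, 4, 5, 6), (0, 10, 5, 5), (2, 75, 12, 160)])
    def test_matches_enumeration_oracle(self, table):
        res = proportion_test(TwoByTwoTable(*table))
        assert res.p == pytest.approx(exact_fisher_two_sided(*table), rel=1e-6)

    def test_or_inverts_on_row_swap(self):
        fwd = proportion_test(TwoByTwoTable(3, 7, 6, 2))
        rev = proportion_test(TwoByTwoTable(6, 2, 3, 7))
        assert fwd.odds_ratio == pytest.approx(1 / rev.odds_ratio)
        assert fwd.p == pytest.approx(rev.p)

    def test_zero_cells(self):
        assert np.isinf(proportion_test(TwoByTwoTable(3, 0, 2, 5)).odds_ratio)
        assert proportion_test(TwoByTwoTable(0, 4, 3, 5)).odds_ratio == 0.0
        assert np.isnan(proportion_test(TwoByTwoTable(0, 4, 0, 5)).odds_ratio)
        with pytest.raises(ValueError, match="empty table"):
            TwoByTwoTable(0, 0, 0, 0)


class TestRunGroupAnalysis:
    def make_two_group(self, seed=0):
        from bindgap import synthgen

        config = synthgen.ExprSimConfig(
            n_genes=10,
            samples_per_stage=8,
            effect_profiles={"RHOA": {"Asian": {"I": 3.0}}},
            seed=seed,
        )
        ds, _ = synthgen.gen_expression(config)
        return exprstats.log_transform(ds)

    def test_singleton_matches_per_gene_ops(self):
        ds = self.make_two_group()
        table = run_group_analysis(ds, ["RHOA"], ["Asian"], n_perm=100, seed=5)
        assert len(table) == 1
        row = table.iloc[0]
        ref = one_way_anova(ds, "RHOA", group="Asian")
        assert row["f_obs"] == pytest.approx(ref.f)
        assert row["p_anova"] == pytest.approx(ref.p)
        perm = permutation_f_test(ds, "RHOA", n_perm=100, seed=int(row["seed"]), group="Asian")
        assert row["p_empirical"] == perm.p_empirical

    def test_planted_effect_found_in_planted_group_only(self):
        ds = self.make_two_group(seed=3)
        table = run_group_analysis(ds, ["RHOA"], ["Asian", "Caucasian"], n_perm=400, seed=7)
        by_group = table.set_index("group")
        assert by_group.loc["Asian", "p_empirical"] <= 0.05
        assert by_group.loc["Caucasian", "p_empirical"] > 0.05
        assert by_group.loc["Asian", "contrast_estimate"] > 0  # Stage I up

    def test_unknown_gene_and_group(self):
        ds = self.make_two_group()
        with pytest.raises(KeyError, match="unknown gene"):
            run_group_analysis(ds, ["NOPE"], ["Asian"], n_perm=10)
        with pytest.raises(KeyError, match="unknown group"):
            run_group_analysis(ds, ["RHOA"], ["Martian"], n_perm=10)

    def test_parametric_only_when_no_perms(self):
        ds = self.make_two_group()
        table = run_group_analysis(ds, ["RHOA"], ["Asian"], n_perm=0)
        assert "p_empirical" not in table.columns
        assert "p_anova" in table.columns


@settings(derandomize=True, max_examples=30)
@given(
    shift=st.floats(-50, 50, allow_nan=False),
    scale=st.floats(0.1, 10, allow_nan=False),
)
def test_f_statistic_affine_invariance(shift, scale):
    """F is invariant to y -> scale*y + shift (scale > 0)."""
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    codes = np.array([0, 0, 1, 1, 2, 2])
    base = anova_from_arrays(y, codes).f
    moved = anova_from_arrays(scale * y + shift, codes).f
    assert moved == pytest.approx(base, rel=1e-8)
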