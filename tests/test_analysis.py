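"""Response tables, pooled ANOVA, additive prediction and confirmation CIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsto.analysis import (
    DegenerateVarianceError,
    PoolingError,
    anova,
    auto_pool,
    confidence_halfwidth,
    f_pvalue,
    f_quantile,
    predict_additive,
    response_table,
    select_best_levels,
    significant_factors,
)
from tsto.design import FactorSpec, get_array, make_plan


@pytest.fixture(scope="module")
def rt1_mean(stage1_plan, stage1_summary):
    return response_table(stage1_plan, stage1_summary.per_run_mean, "mean")


@pytest.fixture(scope="module")
def rt1_sn(stage1_plan, stage1_summary):
    return response_table(stage1_plan, stage1_summary.per_run_sn, "sn")


@pytest.fixture(scope="module")
def anova1_mean(stage1_plan, stage1_summary):
    pooled = {"hidden_layers", "learning_rate", "momentum_rate", "hidden_nodes"}
    return anova(stage1_plan, stage1_summary.per_run_mean, pooled)


@pytest.fixture(scope="module")
def anova1_sn(stage1_plan, stage1_summary):
    pooled = {"hidden_layers", "learning_rate", "momentum_rate", "hidden_nodes"}
    return anova(stage1_plan, stage1_summary.per_run_sn, pooled)


@pytest.fixture(scope="module")
def anova2_mean(stage2_plan, stage2_summary):
    return anova(stage2_plan, stage2_summary.per_run_mean, {"hidden_nodes"})


@pytest.fixture(scope="module")
def anova2_sn(stage2_plan, stage2_summary):
    return anova(stage2_plan, stage2_summary.per_run_sn, {"hidden_nodes"})


class TestResponseTable:
    def test_screening_activation_level_means_and_rank(self, rt1_mean):
        assert rt1_mean.level_means["activation"] == pytest.approx(
            (0.4968, 0.6587, 0.6443), abs=1e-4
        )
        assert rt1_mean.effect["activation"] == pytest.approx(0.1619, abs=1e-4)
        assert rt1_mean.rank["activation"] == 1
        assert rt1_mean.rank["optimizer"] == 2
        assert rt1_mean.rank["hidden_layers"] == 6

    def test_screening_sn_effects(self, rt1_sn):
        assert rt1_sn.effect["activation"] == pytest.approx(2.3102, abs=5e-4)
        assert rt1_sn.effect["optimizer"] == pytest.approx(2.2924, abs=5e-4)
        assert rt1_sn.level_means["activation"][1] == pytest.approx(
            -3.7673, abs=5e-4
        )

    def test_refined_stage_effects_and_ranks(self, stage2_plan, stage2_summary):
        rt = response_table(stage2_plan, stage2_summary.per_run_mean)
        assert rt.effect["learning_rate"] == pytest.approx(0.0023, abs=1e-4)
        assert rt.effect["momentum_rate"] == pytest.approx(0.0017, abs=1e-4)
        assert rt.effect["hidden_nodes"] == pytest.approx(0.0012, abs=1e-4)
        assert [rt.rank[f] for f in ("learning_rate", "momentum_rate", "hidden_nodes")] == [1, 2, 3]

    def test_constant_response_zero_effects_stable_ranks(self, stage2_plan):
        per_run = {r: 0.5 for r in stage2_plan.runs}
        rt = response_table(stage2_plan, per_run)
        assert all(e == 0 for e in rt.effect.values())
        # ties broken by declaration order
        assert [rt.rank[f] for f in stage2_plan.factor_names] == [1, 2, 3]

    def test_invariant_under_run_relabelling(self, stage1_plan, stage1_summary):
        # averaging per level ignores run order: feed the same map, shuffled
        items = list(stage1_summary.per_run_mean.items())
        shuffled = dict(reversed(items))
        rt_a = response_table(stage1_plan, stage1_summary.per_run_mean)
        rt_b = response_table(stage1_plan, shuffled)
        assert rt_a.level_means == rt_b.level_means


class TestAnova:
    def test_screening_accuracy_anova(self, anova1_mean):
        t = anova1_mean
        assert t.error_df == 13
        assert t.error_ms == pytest.approx(0.003901, abs=2e-6)
        assert t.row("activation").ss == pytest.approx(0.096382, abs=5e-5)
        assert t.row("activation").f == pytest.approx(12.35, abs=0.05)
        assert t.row("activation").p == pytest.approx(0.001, abs=5e-4)
        assert t.row("optimizer").f == pytest.approx(12.23, abs=0.05)
        assert 100 * t.r_squared == pytest.approx(79.09, abs=0.05)
        assert 100 * t.r_squared_adj == pytest.approx(72.65, abs=0.05)
        assert t.row("hidden_layers").pooled
        assert t.row("hidden_layers").f is None

    def test_screening_sn_anova(self, anova1_sn):
        t = anova1_sn
        assert t.error_ms == pytest.approx(0.815, abs=5e-4)
        assert t.row("activation").f == pytest.approx(11.78, abs=0.05)
        assert 100 * t.r_squared == pytest.approx(78.27, abs=0.05)

    def test_refined_accuracy_anova(self, anova2_mean):
        t = anova2_mean
        assert t.error_df == 4
        assert t.row("learning_rate").f == pytest.approx(5.94, abs=0.05)
        assert round(t.row("learning_rate").p, 2) == 0.06

    def test_refined_sn_anova(self, anova2_sn):
        t = anova2_sn
        assert t.row("learning_rate").ss == pytest.approx(0.001133, abs=5e-5)
        assert t.row("learning_rate").f == pytest.approx(6.07, abs=0.05)

    def test_pooling_oracle_equivalence(self, stage1_plan, stage1_summary):
        # error SS under pooling == unpooled error SS + pooled factors' SS
        full = anova(stage1_plan, stage1_summary.per_run_mean, set())
        pooled_names = {"hidden_layers", "learning_rate", "momentum_rate", "hidden_nodes"}
        pooled = anova(stage1_plan, stage1_summary.per_run_mean, pooled_names)
        expected = full.error_ss + sum(full.row(n).ss for n in pooled_names)
        assert pooled.error_ss == pytest.approx(expected, rel=1e-12)
        assert pooled.error_df == full.error_df + sum(
            full.row(n).df for n in pooled_names
        )

    def test_decomposition_identity(self, stage1_plan, stage1_summary):
        t = anova(stage1_plan, stage1_summary.per_run_mean, set())
        total = sum(r.ss for r in t.rows) + t.error_ss
        assert total == pytest.approx(t.total_ss, rel=1e-10)
        assert sum(r.df for r in t.rows) + t.error_df == t.total_df

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0.05, 0.95), min_size=9, max_size=9))
    def test_decomposition_identity_on_random_responses(self, stage2_plan, ys):
        per_run = {r: ys[r - 1] for r in stage2_plan.runs}
        if len(set(ys)) == 1:
            return
        t = anova(stage2_plan, per_run, set())
        total = sum(r.ss for r in t.rows) + t.error_ss
        assert total == pytest.approx(t.total_ss, rel=1e-9, abs=1e-15)

    def test_auto_pool_retains_top_two_by_ss(self, stage1_plan, stage1_summary):
        pooled = auto_pool(stage1_plan, stage1_summary.per_run_mean, retain_top_k=2)
        assert pooled == {"hidden_layers", "learning_rate", "momentum_rate", "hidden_nodes"}

    def test_error_df_zero_raises(self):
        # 4 three-level factors on L9 leave no residual DF when none pooled
        fs = [FactorSpec(n, "numeric-integer", (1, 2, 3)) for n in "abcd"]
        plan = make_plan(fs, get_array("L9(3^4)"), {n: i + 1 for i, n in enumerate("abcd")})
        per_run = {r: float(r) for r in plan.runs}
        with pytest.raises(PoolingError):
            anova(plan, per_run, set())

    def test_degenerate_variance_raises(self, stage2_plan):
        with pytest.raises(DegenerateVarianceError):
            anova(stage2_plan, {r: 0.7 for r in stage2_plan.runs}, {"hidden_nodes"})


class TestFDistribution:
    @pytest.mark.parametrize(
        "alpha, df1, df2, expected",
        [(0.05, 1, 13, 4.6672), (0.05, 1, 4, 7.7086)],
    )
    def test_quantiles_match_published_critical_values(
        self, alpha, df1, df2, expected
    ):
        assert f_quantile(alpha, df1, df2) == pytest.approx(expected, abs=5e-4)

    def test_pvalue_for_screening_f(self):
        assert f_pvalue(12.35, 2, 13) == pytest.approx(0.001, abs=5e-4)

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(0.005, 0.5),
        st.integers(1, 10),
        st.integers(1, 30),
    )
    def test_quantile_pvalue_mutual_inverse(self, alpha, df1, df2):
        q = f_quantile(alpha, df1, df2)
        assert f_pvalue(q, df1, df2) == pytest.approx(alpha, abs=1e-6)

    def test_invalid_df_raises(self):
        with pytest.raises(ValueError):
            f_quantile(0.05, 0, 4)
        with pytest.raises(ValueError):
            f_quantile(1.5, 1, 4)


class TestSignificance:
    def test_screening_significant_factors(self, anova1_mean):
        assert significant_factors(anova1_mean, 0.1) == {"activation", "optimizer"}

    def test_refined_significant_factors(self, anova2_mean):
        assert significant_factors(anova2_mean, 0.1) == {
            "learning_rate",
            "momentum_rate",
        }

    def test_strict_alpha_empties_the_set(self, anova2_mean):
        assert significant_factors(anova2_mean, 1e-6) == set()


class TestAdditivePrediction:
    def test_screening_predictions(self, rt1_mean, rt1_sn):
        chosen = {"activation": "tanh", "optimizer": "sgd"}
        assert predict_additive(rt1_mean, chosen).value == pytest.approx(
            0.7166, abs=1e-3
        )
        assert predict_additive(rt1_sn, chosen).value == pytest.approx(
            -2.919, abs=5e-3
        )

    def test_empty_selection_returns_grand_mean(self, rt1_mean):
        assert predict_additive(rt1_mean, {}).value == pytest.approx(0.5999, abs=1e-4)

    def test_unknown_level_raises(self, rt1_mean):
        with pytest.raises(KeyError):
            predict_additive(rt1_mean, {"activation": "softmax"})

    def test_refined_predictions(self, stage2_plan, stage2_summary):
        rt_m = response_table(stage2_plan, stage2_summary.per_run_mean)
        rt_s = response_table(stage2_plan, stage2_summary.per_run_sn)
        chosen = {"learning_rate": 0.25, "momentum_rate": 0.85}
        assert predict_additive(rt_m, chosen).value == pytest.approx(0.7399, abs=1e-3)
        assert predict_additive(rt_s, chosen).value == pytest.approx(-2.616, abs=5e-3)


class TestConfidenceInterval:
    def test_screening_ci_halfwidths(self, anova1_mean, anova1_sn):
        ci_m = confidence_halfwidth(
            anova1_mean, 18, ["activation", "optimizer"], r=5
        )
        assert ci_m.n_eff == pytest.approx(3.6)
        assert ci_m.half_width == pytest.approx(0.0933, abs=1e-3)
        ci_s = confidence_halfwidth(
            anova1_sn, 18, ["activation", "optimizer"], r=5
        )
        assert ci_s.half_width == pytest.approx(1.3481, abs=5e-3)

    def test_refined_sn_ci(self, anova2_sn):
        ci = confidence_halfwidth(
            anova2_sn, 9, ["learning_rate", "momentum_rate"], r=5
        )
        assert ci.n_eff == pytest.approx(1.8)
        assert ci.half_width == pytest.approx(0.0233, abs=5e-3)

    def test_interval_and_containment(self, anova1_mean):
        ci = confidence_halfwidth(
            anova1_mean, 18, ["activation", "optimizer"], r=5, center=0.7166
        )
        lo, hi = ci.interval
        assert (lo, hi) == pytest.approx((0.6233, 0.8099), abs=1e-3)
        assert ci.contains(0.7383)
        assert not ci.contains(0.5)

    def test_invalid_r_raises(self, anova1_mean):
        with pytest.raises(ValueError):
            confidence_halfwidth(anova1_mean, 18, ["activation"], r=0)


class TestBestLevels:
    def test_screening_best_levels(self, rt1_mean, rt1_sn):
        assert select_best_levels(rt1_mean, rt1_sn) == {
            "hidden_layers": 4,
            "activation": "tanh",
            "optimizer": "sgd",
            "learning_rate": 0.3,
            "momentum_rate": 0.9,
            "hidden_nodes": 8,
        }

    def test_refined_best_levels(self, stage2_plan, stage2_summary):
        rt_m = response_table(stage2_plan, stage2_summary.per_run_mean)
        rt_s = response_table(stage2_plan, stage2_summary.per_run_sn)
        assert select_best_levels(rt_m, rt_s) == {
            "learning_rate": 0.25,
            "momentum_rate": 0.85,
            "hidden_nodes": 10,
        }

    def test_mean_tie_broken_by_sn(self):
        from tsto.analysis import ResponseTable

        common = dict(
            kind="mean",
            grand_mean=0.5,
            factors=("f",),
            levels={"f": (1, 2)},
        )
        rt_mean = ResponseTable(level_means={"f": (0.5, 0.5)}, **common)
        rt_sn = ResponseTable(
            level_means={"f": (-3.0, -2.0)},
            **{**common, "kind": "sn"},
        )
        assert select_best_levels(rt_mean, rt_sn) == {"f": 2}
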