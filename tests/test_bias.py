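"""ANOVA F, relativized F, correlation curves, bands, recommendations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gardenbias import (
    GrowthParams,
    PosteriorDraws,
    correlation_curve,
    group_summary,
    make_grid_layout,
    make_initial_sizes,
    make_posterior_draws,
    one_way_f,
    percentile_band,
    recommend_min_distance,
    relative_f,
    run_sweep,
    summarize_sweep,
)
from gardenbias.bias import NO_RECOMMENDATION, DegenerateDesignError
from gardenbias.simulate import SweepResult


def f_oracle(response, groups):
    """Textbook sums-of-squares F computed with explicit loops."""
    response = np.asarray(response, float)
    labels = sorted(set(groups))
    grand = response.mean()
    ssb = sum(
        (groups == g).sum() * (response[groups == g].mean() - grand) ** 2
        for g in labels
    )
    ssw = sum(
        ((response[groups == g] - response[groups == g].mean()) ** 2).sum()
        for g in labels
    )
    df1, df2 = len(labels) - 1, len(response) - len(labels)
    return (ssb / df1) / (ssw / df2)


class TestOneWayF:
    def test_hand_example(self):
        res = one_way_f([1.0, 2.0, 3.0, 4.0], np.array(["A", "A", "B", "B"]))
        assert res.f_value == pytest.approx(8.0)
        assert (res.df1, res.df2) == (1, 2)

    def test_constant_response_gives_zero(self):
        res = one_way_f(np.ones(10), np.repeat([0, 1], 5))
        assert res.f_value == 0.0

    def test_zero_within_variance_gives_inf(self):
        res = one_way_f([1, 1, 2, 2], np.array([0, 0, 1, 1]))
        assert np.isinf(res.f_value)

    def test_study_scale_degrees_of_freedom(self, default_layout):
        live = default_layout.live_subset()
        rng = np.random.default_rng(0)
        res = one_way_f(rng.normal(size=live.n_positions), live.group)
        assert (res.df1, res.df2) == (5, 442)

    def test_agrees_with_oracle_and_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            n = int(rng.integers(k + 2, 40))
            groups = np.concatenate([np.arange(k), rng.integers(0, k, n - k)])
            response = rng.normal(size=n) + 0.5 * groups
            got = one_way_f(response, groups)
            assert got.f_value == pytest.approx(f_oracle(response, groups),
                                                rel=1e-10)
            scipy_f = stats.f_oneway(
                *[response[groups == g] for g in range(k)]
            ).statistic
            assert got.f_value == pytest.approx(scipy_f, rel=1e-9)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(9)
        groups = rng.integers(0, 3, 30)
        resp = rng.normal(size=30) + groups
        f0 = one_way_f(resp, groups).f_value
        assert one_way_f(resp + 7.3, groups).f_value == pytest.approx(f0)
        assert one_way_f(2.5 * resp, groups).f_value == pytest.approx(f0)

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateDesignError):
            one_way_f([1, 2, 3], np.zeros(3))


def toy_sweep(mu_full, mu_base, groups, distances=(1.0,)):
    mu_full = np.asarray(mu_full, float)
    mu_base = np.asarray(mu_base, float)
    return SweepResult(
        distances=np.asarray(distances), mu_full=mu_full, mu_base=mu_base,
        phi=np.zeros_like(mu_full), noise_mode="none",
        groups=np.asarray(groups), sizes=np.ones(mu_full.shape[-1]),
    )


class TestRelativeF:
    def test_zero_difference_gives_all_zero(self):
        rng = np.random.default_rng(1)
        groups = np.repeat([0, 1, 2], 4)
        base = rng.normal(size=(1, 3, 12)) + groups
        sw = toy_sweep(base.copy(), base, groups)
        np.testing.assert_array_equal(relative_f(sw), np.zeros(3))

    def test_three_draw_toy_matches_explicit_oracle(self):
        rng = np.random.default_rng(2)
        groups = np.repeat([0, 1], 5)
        mu_base = rng.normal(size=(1, 3, 10)) + groups
        mu_full = mu_base + rng.normal(scale=0.5, size=(1, 3, 10))
        sw = toy_sweep(mu_full, mu_base, groups)
        got = relative_f(sw)
        base_fs = [f_oracle(mu_base[0, k], groups) for k in range(3)]
        want = [
            f_oracle(mu_full[0, k] - mu_base[0, k], groups) / np.mean(base_fs)
            for k in range(3)
        ]
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_declines_between_dense_and_sparse_gardens(self, default_layout,
                                                       default_sizes):
        draws = make_posterior_draws(n_draws=40, seed=21)
        sw = run_sweep(default_layout, default_sizes, draws,
                       distances=[0.5, 4.0], noise_mode="independent", seed=22)
        rf_dense = relative_f(sw.at_distance(0.5)).mean()
        rf_sparse = relative_f(sw.at_distance(4.0)).mean()
        assert rf_sparse < rf_dense


class TestCorrelationCurve:
    def test_identical_predictions_give_r_one(self):
        groups = np.repeat([0, 1], 4)
        base = np.random.default_rng(0).normal(size=(2, 3, 8))
        sw = toy_sweep(base.copy(), base, groups, distances=(0.5, 1.0))
        curve = correlation_curve(sw)
        np.testing.assert_array_equal(curve["r_mean"], [1.0, 1.0])

    def test_matches_textbook_pearson(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.1, 1.9, 3.0])
        sw = toy_sweep(y[None, None], x[None, None], np.array([0, 0, 1]))
        got = correlation_curve(sw)["r_mean"][0]
        mx, my = x.mean(), y.mean()
        want = (((x - mx) * (y - my)).sum()
                / np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum()))
        assert got == pytest.approx(want, rel=1e-12)

    def test_constant_differing_vector_is_undefined(self):
        sw = toy_sweep(np.full((1, 1, 4), 2.0), np.arange(4.0)[None, None],
                       np.array([0, 0, 1, 1]))
        with pytest.raises(ValueError):
            correlation_curve(sw)

    def test_mean_r_rises_with_distance(self, default_layout, default_sizes,
                                        small_draws):
        sw = run_sweep(default_layout, default_sizes, small_draws,
                       noise_mode="none", seed=0)
        curve = correlation_curve(sw)
        assert np.all(curve["r_mean"].to_numpy() <= 1.0)
        rho = stats.spearmanr(curve["distance"], curve["r_mean"]).statistic
        assert rho >= 0
        assert curve["r_mean"].iloc[-1] > curve["r_mean"].iloc[0]


class TestPercentileBand:
    def test_constant_samples_collapse(self):
        assert percentile_band(np.full(5, 3.3), 0.95) == (3.3, 3.3)

    def test_standard_normal_quantiles(self):
        z = np.random.default_rng(3).standard_normal(100_000)
        lo, hi = percentile_band(z, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_bands_nest(self):
        x = np.random.default_rng(4).normal(size=500)
        lo68, hi68 = percentile_band(x, 0.68)
        lo95, hi95 = percentile_band(x, 0.95)
        assert lo95 <= lo68 <= hi68 <= hi95

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_band(np.array([]), 0.5)


class TestRecommendation:
    def make_curve(self, lows):
        return pd.DataFrame({
            "distance": np.arange(1, len(lows) + 1, dtype=float),
            "r_mean": np.ones(len(lows)),
            "r_lo68": lows,
        })

    def test_perfect_correlation_recommends_smallest(self):
        assert recommend_min_distance(self.make_curve([1.0, 1.0])) == 1.0

    def test_no_qualifying_distance_is_sentinel(self):
        rec = recommend_min_distance(self.make_curve([0.5, 0.9]))
        assert rec is NO_RECOMMENDATION

    def test_first_crossing_selected(self):
        rec = recommend_min_distance(self.make_curve([0.2, 0.995, 0.97, 0.999]))
        assert rec == 2.0


class TestGroupSummary:
    def test_symmetric_setup_ties_all_groups(self):
        lay = make_grid_layout(n_positions=16, n_cols=4, n_dead=0, seed=0)
        sizes = np.full(16, 0.05)
        params = GrowthParams(alpha=np.ones(6), beta=np.full(6, 0.5),
                              gamma=np.zeros(6), c=np.ones(6), b=-0.5,
                              sigma=0.0)
        sw = run_sweep(lay, sizes, PosteriorDraws.from_list([params]),
                       distances=[1.0], noise_mode="none", seed=0)
        gs = group_summary(sw)
        assert gs["mean_growth"].nunique() == 1

    def test_crowding_reorders_groups_between_densities(
            self, default_layout, default_sizes, small_draws):
        sw = run_sweep(default_layout, default_sizes, small_draws,
                       distances=[0.5, 4.0], noise_mode="none", seed=0)
        dense = group_summary(sw.at_distance(0.5)).set_index("group")["rank"]
        sparse = group_summary(sw.at_distance(4.0)).set_index("group")["rank"]
        # tolerant tetraploids overtake sensitive diploids when crowded
        assert (dense != sparse).any()


def test_summarize_sweep_shapes_and_recommendation(default_layout,
                                                   default_sizes, small_draws):
    f_sw = run_sweep(default_layout, default_sizes, small_draws,
                     distances=[0.5, 2.0, 4.0], noise_mode="independent",
                     seed=1)
    r_sw = run_sweep(default_layout, default_sizes, small_draws,
                     distances=[0.5, 2.0, 4.0], noise_mode="none", seed=1)
    summary, groups, rec = summarize_sweep(f_sw, r_sw)
    assert len(summary) == 3
    assert {"rel_f_mean", "rel_f_lo68", "rel_f_hi95", "r_mean",
            "r_lo68"} <= set(summary.columns)
    # 68% band nested in 95% band at every distance
    assert (summary["rel_f_lo95"] <= summary["rel_f_lo68"]).all()
    assert (summary["rel_f_hi68"] <= summary["rel_f_hi95"]).all()
    assert len(groups) == 3 * 6
    assert rec is None or rec in [0.5, 2.0, 4.0]
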