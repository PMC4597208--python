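import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crpsig import (
    DegenerateDataError,
    RiskModelPair,
    analytic_ci,
    backward_select,
    bootstrap_ci,
    build_model_pair,
    cfnri,
    fit_logistic,
    idi,
    nri_curve,
)


def random_pair(rng, n=60):
    e = rng.random(n) < 0.6
    if e.all() or not e.any():
        e[0], e[1] = True, False
    return RiskModelPair(p_base=rng.random(n), p_new=rng.random(n), event=e)


def _design(x):
    return pd.DataFrame({"x": np.asarray(x, dtype=float)})


class TestFitLogistic:
    def test_two_by_two_closed_form_odds_ratio(self):
        # saturated 2x2: OR = (a*d)/(b*c) with a=events@x1, b=events@x0, ...
        a, b, c, d = 20, 10, 15, 30
        x = np.array([1.0] * (a + c) + [0.0] * (b + d))
        y = np.array([True] * a + [False] * c + [True] * b + [False] * d)
        fit = fit_logistic(_design(x), y)
        assert fit.table.loc["x", "odds_ratio"] == pytest.approx(a * d / (b * c), abs=1e-4)

    def test_null_covariate_odds_ratio_near_one(self):
        rng = np.random.default_rng(10)
        n = 2000
        x = rng.standard_normal(n)
        y = rng.random(n) < 0.5
        fit = fit_logistic(_design(x), y)
        assert 0.85 <= fit.table.loc["x", "odds_ratio"] <= 1.18

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.ones(10), -np.ones(10)])
        y = x > 0
        fit = fit_logistic(_design(x), y)
        assert fit.separation

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(_design(np.ones(20)), np.arange(20) % 2 == 0)


class TestBackwardSelect:
    def _strong(self, rng, n=300):
        x = rng.standard_normal(n)
        y = rng.random(n) < 1 / (1 + np.exp(-2 * x))
        return x, y

    def test_all_significant_model_unchanged(self):
        rng = np.random.default_rng(2)
        x, y = self._strong(rng)
        fit = backward_select(_design(x), y)
        assert fit.terms == ["x"] and fit.removed == ()

    def test_noise_covariate_removed(self):
        rng = np.random.default_rng(3)
        x, y = self._strong(rng)
        design = _design(x)
        design["noise"] = rng.standard_normal(len(x))
        fit = backward_select(design, y)
        assert fit.terms == ["x"] and "noise" in fit.removed

    def test_nothing_retained_gives_intercept_only(self):
        rng = np.random.default_rng(4)
        design = pd.DataFrame({"a": rng.standard_normal(200), "b": rng.standard_normal(200)})
        y = rng.random(200) < 0.5
        fit = backward_select(design, y)
        assert fit.terms == [] and set(fit.removed) == {"a", "b"}
        assert fit.table.loc["const", "odds_ratio"] == pytest.approx(
            y.mean() / (1 - y.mean()), rel=1e-6
        )


class TestBuildModelPair:
    def _cohort(self, rng, n=120):
        age = 50 + 10 * rng.standard_normal(n)
        score = rng.random(n)
        logit = 0.06 * (age - 50) + 2.5 * (score - 0.5)
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        return pd.DataFrame({"donor_age": age}), score, y

    def test_constant_signature_leaves_risks_unchanged(self):
        rng = np.random.default_rng(5)
        cov, _, y = self._cohort(rng)
        pair, _, _ = build_model_pair(cov, np.full(len(y), 0.5), y)
        np.testing.assert_allclose(pair.p_new, pair.p_base, atol=1e-6)

    def test_event_indicator_score_flags_separation(self):
        rng = np.random.default_rng(6)
        cov, _, y = self._cohort(rng)
        _, _, new_fit = build_model_pair(cov, y.astype(float), y)
        assert new_fit.separation

    def test_informative_signature_raises_event_risks(self):
        rng = np.random.default_rng(7)
        cov, score, y = self._cohort(rng)
        pair, _, _ = build_model_pair(cov, score, y)
        assert pair.p_new[pair.event].mean() > pair.p_base[pair.event].mean()


class TestCfnri:
    def _table4_pair(self):
        """Risk pair realizing the published reclassification counts:
        events 50 up / 9 down of 59; non-events 13 up / 19 down of 32."""
        e_dir = np.array([1] * 50 + [-1] * 9)
        n_dir = np.array([1] * 13 + [-1] * 19)
        p_base = np.full(91, 0.5)
        p_new = 0.5 + 0.2 * np.concatenate([e_dir, n_dir])
        event = np.array([True] * 59 + [False] * 32)
        return RiskModelPair(p_base, p_new, event)

    def test_event_component_from_published_counts(self):
        res = cfnri(self._table4_pair())
        assert res.events_up == 50 and res.events_down == 9
        assert res.cfnri_events == pytest.approx(100 * (50 - 9) / 59)
        assert round(res.cfnri_events, 1) == 69.5

    def test_nonevent_component_from_published_counts(self):
        res = cfnri(self._table4_pair())
        assert res.cfnri_nonevents == pytest.approx(100 * (19 - 13) / 32)
        assert round(res.cfnri_nonevents, 1) == 18.8

    def test_maximum_is_200_percent(self):
        p_base = np.full(10, 0.5)
        p_new = np.concatenate([np.full(6, 0.9), np.full(4, 0.1)])
        event = np.array([True] * 6 + [False] * 4)
        assert cfnri(RiskModelPair(p_base, p_new, event)).cfnri_total == 200.0

    def test_exact_ties_move_neither_way(self):
        pair = RiskModelPair(
            p_base=np.array([0.5, 0.5, 0.5]),
            p_new=np.array([0.5, 0.6, 0.4]),
            event=np.array([True, True, False]),
        )
        res = cfnri(pair)
        assert res.events_up == 1 and res.events_down == 0 and res.nonevents_down == 1


class TestNriCurve:
    def test_zero_threshold_matches_category_free_value(self):
        rng = np.random.default_rng(11)
        pair = random_pair(rng)
        curve = nri_curve(pair, [0.0, 0.1])
        assert curve.loc[0, "cfnri_total"] == pytest.approx(cfnri(pair).cfnri_total)

    def test_threshold_beyond_max_change_zeroes_components(self):
        rng = np.random.default_rng(12)
        pair = random_pair(rng)
        t = np.abs(pair.p_new - pair.p_base).max() + 0.01
        row = nri_curve(pair, [t]).iloc[0]
        assert row["cfnri_events"] == row["cfnri_nonevents"] == row["cfnri_total"] == 0.0

    def test_events_component_halves_between_thresholds(self):
        pair = RiskModelPair(
            p_base=np.array([0.5, 0.5, 0.5]),
            p_new=np.array([0.55, 0.65, 0.4]),
            event=np.array([True, True, False]),
        )
        curve = nri_curve(pair, [0.0, 0.1])
        assert curve.loc[0, "cfnri_events"] == pytest.approx(100.0)
        assert curve.loc[1, "cfnri_events"] == pytest.approx(50.0)


class TestIdi:
    def test_published_components_sum(self):
        # component means fixed to the published values; the total must be
        # their sum, 0.3864
        p_base = np.concatenate([np.full(59, 0.5), np.full(32, 0.5)])
        p_new = np.concatenate([np.full(59, 0.5 + 0.1282), np.full(32, 0.5 - 0.2582)])
        event = np.array([True] * 59 + [False] * 32)
        res = idi(RiskModelPair(p_base, p_new, event))
        assert res.idi_events == pytest.approx(0.1282)
        assert res.idi_nonevents == pytest.approx(0.2582)
        assert res.idi_total == pytest.approx(0.3864)

    def test_identical_models_zero(self):
        rng = np.random.default_rng(13)
        p = rng.random(20)
        e = np.arange(20) % 2 == 0
        res = idi(RiskModelPair(p, p.copy(), e))
        assert res.idi_events == res.idi_nonevents == res.idi_total == 0.0

    def test_mean_arithmetic_example(self):
        pair = RiskModelPair(
            p_base=np.array([0.6, 0.8, 0.4]),
            p_new=np.array([0.7, 0.9, 0.3]),
            event=np.array([True, True, False]),
        )
        res = idi(pair)
        assert res.idi_events == pytest.approx(0.1)
        assert res.idi_nonevents == pytest.approx(0.1)
        assert res.idi_total == pytest.approx(0.2)


class TestIdentities:
    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_idi_equals_discrimination_slope_difference(self, seed):
        pair = random_pair(np.random.default_rng(seed))
        res = idi(pair)
        e = pair.event
        slope_new = pair.p_new[e].mean() - pair.p_new[~e].mean()
        slope_base = pair.p_base[e].mean() - pair.p_base[~e].mean()
        assert res.idi_total == pytest.approx(slope_new - slope_base, abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_component_sums_and_swap_antisymmetry(self, seed):
        pair = random_pair(np.random.default_rng(seed))
        res_n, res_i = cfnri(pair), idi(pair)
        assert res_n.cfnri_total == res_n.cfnri_events + res_n.cfnri_nonevents
        assert res_i.idi_total == res_i.idi_events + res_i.idi_nonevents
        swapped = RiskModelPair(pair.p_new, pair.p_base, pair.event)
        assert cfnri(swapped).cfnri_total == pytest.approx(-res_n.cfnri_total, abs=1e-12)
        assert idi(swapped).idi_total == pytest.approx(-res_i.idi_total, abs=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(14)
        pair = random_pair(rng)
        perm = rng.permutation(len(pair.event))
        shuffled = RiskModelPair(pair.p_base[perm], pair.p_new[perm], pair.event[perm])
        assert cfnri(shuffled).cfnri_total == cfnri(pair).cfnri_total
        assert idi(shuffled).idi_total == pytest.approx(idi(pair).idi_total, abs=1e-15)


class TestBootstrapCI:
    def test_constant_statistic_zero_width(self):
        p_base = np.full(20, 0.5)
        p_new = np.concatenate([np.full(12, 0.9), np.full(8, 0.1)])
        event = np.array([True] * 12 + [False] * 8)
        ci = bootstrap_ci(RiskModelPair(p_base, p_new, event), "cfnri", reps=200, seed=1)
        assert ci["cfnri_total"] == (200.0, 200.0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(15)
        pair = random_pair(rng)
        a = bootstrap_ci(pair, "idi", reps=200, seed=42)
        b = bootstrap_ci(pair, "idi", reps=200, seed=42)
        assert a == b

    def test_analytic_ci_brackets_estimate(self):
        rng = np.random.default_rng(16)
        pair = random_pair(rng, n=120)
        res = idi(pair)
        lo, hi = analytic_ci(pair, "idi")["idi_total"]
        assert lo < res.idi_total < hi

    def test_small_reps_rejected(self):
        rng = np.random.default_rng(17)
        with pytest.raises(ValueError):
            bootstrap_ci(random_pair(rng), "idi", reps=10, seed=0)

    def test_empty_group_rejected(self):
        pair = RiskModelPair(
            p_base=np.array([0.3, 0.4]), p_new=np.array([0.5, 0.6]),
            event=np.array([True, True]),
        )
        with pytest.raises(DegenerateDataError):
            cfnri(pair)
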