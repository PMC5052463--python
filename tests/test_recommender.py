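import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mossense import recommender as rc
from mossense.recommender import (
    Basket,
    Context24h,
    EligibilityRule,
    FeatureRange,
    InterventionState,
    basket_score,
    block_time,
    default_catalog,
    intervention_score,
    personalize_ranges,
    recommend,
    scale_to_range,
)

NO_BONUS = 0.5  # any rng draw > 0.05 skips the chance bonus


class NoBonusRng:
    """Stub rng whose draws never trigger the chance bonus."""

    def random(self):
        return 0.99


def ctx(features=None, at_home=True, slot="morning", t=0):
    return Context24h(features=features or {}, at_home=at_home, slot=slot, t=t)


class TestScaleToRange:
    def test_endpoints_and_midpoint(self):
        assert scale_to_range(0.0, 0.0, 10.0) == 0.0
        assert scale_to_range(10.0, 0.0, 10.0) == 1.0
        assert scale_to_range(5.0, 0.0, 10.0) == 0.5

    def test_clamped(self):
        assert scale_to_range(-3.0, 0.0, 10.0) == 0.0
        assert scale_to_range(42.0, 0.0, 10.0) == 1.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(rc.RangeError):
            scale_to_range(1.0, 5.0, 5.0)

    @settings(max_examples=50, deadline=None)
    @given(x=st.floats(-1e6, 1e6), lo=st.floats(-1e3, 1e3),
           width=st.floats(1e-3, 1e3))
    def test_image_in_unit_interval(self, x, lo, width):
        assert 0.0 <= scale_to_range(x, lo, lo + width) <= 1.0


class TestBasketScore:
    def test_all_zero_weights(self):
        b = Basket("b", "physical", {"walking_min": 0.0})
        ranges = {"walking_min": FeatureRange("walking_min", 0, 100)}
        assert basket_score(b, ctx({"walking_min": 50.0}), ranges) == 0.0

    def test_single_feature_at_max(self):
        b = Basket("b", "physical", {"walking_min": 1.0})
        ranges = {"walking_min": FeatureRange("walking_min", 0, 100)}
        assert basket_score(b, ctx({"walking_min": 100.0}), ranges) == 1.0

    def test_two_features_direct_evaluation(self):
        # weights (2, -1) on scaled values (0.5, 1.0) -> 0.0
        b = Basket("b", "social", {"f1": 2.0, "f2": -1.0})
        ranges = {"f1": FeatureRange("f1", 0, 10), "f2": FeatureRange("f2", 0, 10)}
        score = basket_score(b, ctx({"f1": 5.0, "f2": 10.0}), ranges)
        assert score == pytest.approx(0.0)

    def test_missing_range_named_in_error(self):
        b = Basket("b", "physical", {"walking_min": 1.0})
        with pytest.raises(rc.RecommenderConfigError, match="walking_min"):
            basket_score(b, ctx({"walking_min": 1.0}), ranges={})

    @settings(max_examples=30, deadline=None)
    @given(w=st.floats(-5, 5), scale=st.floats(0.1, 4))
    def test_linear_in_each_weight(self, w, scale):
        ranges = {"f": FeatureRange("f", 0, 10)}
        context = ctx({"f": 7.0})
        s1 = basket_score(Basket("b", "physical", {"f": w}), context, ranges)
        s2 = basket_score(Basket("b", "physical", {"f": w * scale}), context, ranges)
        assert s2 == pytest.approx(s1 * scale, rel=1e-9, abs=1e-12)


class TestInterventionScore:
    def make(self, ratings=(), cancellations=0, executions=0):
        return InterventionState("iv", "b", ratings=list(ratings),
                                 cancellations=cancellations, executions=executions)

    def test_five_star_never_cancelled(self):
        s = self.make(ratings=[5, 5], executions=2)
        assert intervention_score(s, NO_BONUS) == pytest.approx(0.75)

    def test_full_cancellation_rate(self):
        s = self.make(ratings=[5], cancellations=3, executions=0)
        # 0.75*1 - 0.25*1 = 0.5
        assert intervention_score(s, NO_BONUS) == pytest.approx(0.5)

    def test_mid_values_with_bonus(self):
        s = self.make(ratings=[2, 3], cancellations=1, executions=1)
        # 0.75*0.5 - 0.25*0.5 + 0.5 = 0.75
        assert intervention_score(s, 0.01) == pytest.approx(0.75)

    def test_unrated_uses_neutral_prior(self):
        s = self.make()
        assert s.mean_rating == 3.0 and s.cancellation_rate == 0.0
        assert intervention_score(s, NO_BONUS) == pytest.approx(0.75 * 3 / 5)

    def test_score_bounds_and_bonus_shift(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_r = int(rng.integers(1, 6))
            s = self.make(ratings=rng.integers(1, 6, n_r).tolist(),
                          cancellations=int(rng.integers(0, 5)),
                          executions=int(rng.integers(0, 5)))
            base = intervention_score(s, NO_BONUS)
            assert 0.75 * (1 / 5) - 0.25 - 1e-12 <= base <= 0.75 + 1e-12
            assert intervention_score(s, 0.0) == pytest.approx(base + 0.5)

    def test_bonus_frequency_binomial(self):
        rng = np.random.default_rng(42)
        s = self.make(ratings=[3], executions=1)
        n = 4000
        bonus = sum(intervention_score(s, float(rng.random())) > 0.5 for _ in range(n))
        lo, hi = stats.binom.interval(0.999, n, 0.05)
        assert lo <= bonus <= hi


class TestBlockTime:
    @pytest.mark.parametrize("rating,hours", [(5, 36.0), (1, 180.0), (3, 108.0)])
    def test_direct_values(self, rating, hours):
        assert block_time(rating) == hours

    def test_strictly_decreasing_in_rating(self):
        hours = [block_time(r) for r in range(1, 6)]
        assert all(a > b for a, b in zip(hours, hours[1:]))

    @pytest.mark.parametrize("bad", [0, 6, 2.5])
    def test_invalid_rating(self, bad):
        with pytest.raises(ValueError):
            block_time(bad)

    def test_record_execution_advances_block(self):
        s = InterventionState("iv", "b")
        rc.record_execution(s, rating=4, now=0)
        assert s.blocked_until == 72 * 3_600_000
        assert s.is_blocked(1) and not s.is_blocked(s.blocked_until)


class TestPersonalizeRanges:
    def test_mu_pm_two_sigma(self):
        vals = [6.0, 10.0]  # mu=8, population sd=2 -> [4, 12]
        r = personalize_ranges({"f": vals}, count_features=frozenset())["f"]
        assert (r.x_min, r.x_max) == (4.0, 12.0)
        assert r.source == "personalized"

    def test_degenerate_range_widened(self):
        r = personalize_ranges({"f": [10.0] * 7}, min_width=1.0)["f"]
        assert (r.x_min, r.x_max) == (9.5, 10.5)

    def test_count_features_clipped_at_zero(self):
        r = personalize_ranges({"calls_total": [0.0, 1.0]},
                               count_features=frozenset({"calls_total"}))["calls_total"]
        assert r.x_min == 0.0

    def test_requires_two_days(self):
        with pytest.raises(rc.RangeError):
            personalize_ranges({"f": [1.0]})

    def test_matches_brute_force_over_week(self):
        rng = np.random.default_rng(3)
        week = {f: rng.uniform(0, 100, size=7).tolist() for f in ("a", "b", "c")}
        ranges = personalize_ranges(week, count_features=frozenset())
        for f, vals in week.items():
            mu, sd = np.mean(vals), np.std(vals)
            assert ranges[f].x_min == pytest.approx(mu - 2 * sd)
            assert ranges[f].x_max == pytest.approx(mu + 2 * sd)

    def test_phase2_recovers_phase1_when_week_matches_population(self):
        """A week sitting exactly on the population range endpoints yields a
        personalized range scoring identically to the population range."""
        pop = FeatureRange("walking_min", 30.0, 300.0)
        # days symmetric around the population midpoint with sd = span/4
        mu, sd = 165.0, 67.5
        vals = [mu - sd, mu + sd] * 3 + [mu - sd, mu + sd]
        pers = personalize_ranges({"walking_min": vals},
                                  count_features=frozenset())["walking_min"]
        assert pers.x_min == pytest.approx(pop.x_min)
        assert pers.x_max == pytest.approx(pop.x_max)
        for x in (30.0, 100.0, 300.0):
            assert (scale_to_range(x, pers.x_min, pers.x_max)
                    == pytest.approx(scale_to_range(x, pop.x_min, pop.x_max)))


class TestRecommend:
    def simple_setup(self):
        baskets = default_catalog()
        features = {"walking_min": 10.0, "time_at_home_min": 900.0,
                    "calls_total": 0.0, "sms_total": 1.0, "cal_total": 0.0,
                    "phone_use_min": 300.0, "avg_call_duration_s": 60.0}
        return baskets, ctx(features, at_home=True, slot="morning", t=10**12)

    def test_single_basket_single_intervention(self):
        b = Basket("b", "physical", {"walking_min": 1.0},
                   [InterventionState("only", "b")])
        ranges = {"walking_min": FeatureRange("walking_min", 0, 100)}
        rec = recommend(ctx({"walking_min": 50.0}), [b], ranges,
                        np.random.default_rng(0))
        assert rec.baskets[0].interventions[0].intervention_id == "only"

    def test_lie_down_rule_excludes_away_afternoon(self):
        baskets, _ = self.simple_setup()
        relax = next(b for b in baskets if b.basket_id == "b_relaxation")
        features = {"cal_total": 4.0, "phone_use_min": 400.0}
        context = ctx(features, at_home=False, slot="afternoon")
        ranges = rc.DEFAULT_RANGES
        rec = recommend(context, [relax], ranges, NoBonusRng())
        ids = [iv.intervention_id for iv in rec.baskets[0].interventions]
        assert "iv_liedown_breathing" not in ids
        # at home in the evening it becomes eligible
        rec2 = recommend(ctx(features, at_home=True, slot="evening"),
                         [relax], ranges, NoBonusRng())
        ids2 = [iv.intervention_id for iv in rec2.baskets[0].interventions]
        assert "iv_liedown_breathing" in ids2

    def test_top3_matches_brute_force_sort(self):
        # 5 interventions with distinct injected preference states
        ivs = [InterventionState(f"iv{r}", "b", ratings=[r], executions=1)
               for r in (1, 2, 3, 4, 5)]
        b = Basket("b", "physical", {"f": 1.0}, ivs)
        ranges = {"f": FeatureRange("f", 0, 1)}

        rec = recommend(ctx({"f": 0.5}), [b], ranges, NoBonusRng())
        got = [iv.intervention_id for iv in rec.baskets[0].interventions]
        expected = sorted(ivs, key=lambda s: -intervention_score(s, 0.99))[:3]
        assert got == [s.intervention_id for s in expected] == ["iv5", "iv4", "iv3"]

    def test_blocked_interventions_excluded_and_empty_flag(self):
        now = 10**12
        ivs = [InterventionState(f"iv{i}", "b", blocked_until=now + 1000)
               for i in range(3)]
        b = Basket("b", "social", {"f": 1.0}, ivs)
        ranges = {"f": FeatureRange("f", 0, 1)}
        rec = recommend(ctx({"f": 0.5}, t=now), [b], ranges, np.random.default_rng(0))
        assert rec.baskets[0].all_blocked
        assert rec.baskets[0].interventions == ()

    def test_deterministic_under_fixed_rng(self):
        baskets, context = self.simple_setup()
        r1 = recommend(context, baskets, rc.DEFAULT_RANGES, np.random.default_rng(7))
        r2 = recommend(context, default_catalog(), rc.DEFAULT_RANGES,
                       np.random.default_rng(7))
        assert r1 == r2

    def test_basket_order_and_radius_monotone(self):
        baskets, context = self.simple_setup()
        rec = recommend(context, baskets, rc.DEFAULT_RANGES, np.random.default_rng(0))
        scores = [b.score for b in rec.baskets]
        radii = [b.display_radius for b in rec.baskets]
        assert scores == sorted(scores, reverse=True)
        for (s1, r1), (s2, r2) in zip(zip(scores, radii), zip(scores[1:], radii[1:])):
            if s1 > s2:
                assert r1 > r2

    def test_low_activity_context_prefers_physical_basket(self):
        baskets, context = self.simple_setup()  # sedentary, housebound, no calls
        rec = recommend(context, baskets, rc.DEFAULT_RANGES, np.random.default_rng(0))
        assert rec.baskets[0].domain in ("physical", "social")

    def test_no_baskets_rejected(self):
        with pytest.raises(rc.RecommenderConfigError):
            recommend(ctx(), [], {}, np.random.default_rng(0))


class TestEvaluationEpoch:
    def test_six_hour_boundaries(self):
        h = 3_600_000
        assert rc.evaluation_epoch(0) == 0
        assert rc.evaluation_epoch(6 * h - 1) == 0
        assert rc.evaluation_epoch(6 * h) == 1
        assert rc.evaluation_epoch(24 * h) == 4

    def test_timezone_shifts_phase(self):
        h = 3_600_000
        assert rc.evaluation_epoch(5 * h, tz_offset_hours=1.0) == 1


class TestCatalogPersistence:
    def test_round_trip(self):
        baskets = default_catalog()
        baskets[0].interventions[0].ratings.append(4)
        baskets[0].interventions[0].executions += 1
        doc = rc.catalog_to_dict(baskets)
        back = rc.catalog_from_dict(doc)
        assert back == baskets
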