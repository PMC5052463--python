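"""Two-phase context-sensitive intervention recommender.

Baskets of interventions are scored every 6 hours against the trailing
24-hour context: each weighted feature is scaled to the fraction of its
expected range that the subject reached, and the basket score is the
weighted sum.  Phase 1 uses population ranges; after two weeks of data the
ranges are personalized to the subject's last week (mean +/- 2 sd).  Within
a presented basket the top 3 eligible, unblocked interventions are ranked by
a preference score built from past star ratings, the cancellation rate, and
a 5% chance bonus; a rated intervention is blocked for 36*(6 - rating)
hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .sensor_model import MS_PER_HOUR

CHANCE_BONUS_P = 0.05
CHANCE_BONUS = 0.5
RATING_WEIGHT = 0.75
CANCEL_WEIGHT = 0.25
BLOCK_HOURS_PER_STAR = 36
PRIOR_RATING = 3.0           # unrated interventions score as neutral
TOP_K_INTERVENTIONS = 3
TOP_K_BASKETS = 4            # one slot per domain on the home screen
EVAL_PERIOD_HOURS = 6        # epoch boundaries at local 00/06/12/18

DOMAINS = ("physical", "social", "mindfulness", "relaxation")
INTERACTION_TYPES = ("activity_tracker", "quiz", "checkbox", "button",
                     "mirror", "audio", "multitext", "countdown")


class RangeError(ValueError):
    pass


class RecommenderConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureRange:
    feature: str
    x_min: float
    x_max: float
    source: str = "population"   # {"population", "personalized"}

    def __post_init__(self):
        if not self.x_max > self.x_min:
            raise RangeError(f"{self.feature}: x_max must exceed x_min "
                             f"({self.x_min} >= {self.x_max})")


@dataclass(frozen=True)
class EligibilityRule:
    """Context predicate: None means unconstrained."""
    locations: tuple[str, ...] | None = None   # subset of {"home", "away"}
    slots: tuple[str, ...] | None = None       # subset of {"morning","afternoon","evening"}

    def allows(self, at_home: bool, slot: str) -> bool:
        loc = "home" if at_home else "away"
        if self.locations is not None and loc not in self.locations:
            return False
        if self.slots is not None and slot not in self.slots:
            return False
        return True


@dataclass
class InterventionState:
    intervention_id: str
    basket_id: str
    type: str = "checkbox"
    duration_min: float = 5.0
    rule: EligibilityRule = field(default_factory=EligibilityRule)
    ratings: list[int] = field(default_factory=list)
    cancellations: int = 0
    executions: int = 0
    blocked_until: int | None = None

    def __post_init__(self):
        if self.type not in INTERACTION_TYPES:
            raise RecommenderConfigError(f"unknown interaction type {self.type!r}")
        if any(not 1 <= r <= 5 for r in self.ratings):
            raise RecommenderConfigError("ratings must be integers in 1..5")
        if self.cancellations < 0 or self.executions < 0:
            raise RecommenderConfigError("attempt counts must be >= 0")

    @property
    def mean_rating(self) -> float:
        return float(np.mean(self.ratings)) if self.ratings else PRIOR_RATING

    @property
    def cancellation_rate(self) -> float:
        attempts = self.executions + self.cancellations
        return self.cancellations / attempts if attempts else 0.0

    def is_blocked(self, now: int) -> bool:
        return self.blocked_until is not None and now < self.blocked_until


@dataclass
class Basket:
    basket_id: str
    domain: str
    weights: dict[str, float]
    interventions: list[InterventionState] = field(default_factory=list)

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise RecommenderConfigError(f"unknown domain {self.domain!r}")


@dataclass(frozen=True)
class Context24h:
    """Feature values over the trailing 24 hours plus the current situation."""
    features: Mapping[str, float]
    at_home: bool
    slot: str
    t: int


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def scale_to_range(x: float, x_min: float, x_max: float) -> float:
    """Fraction of the [x_min, x_max] range reached by x, clamped to [0, 1]."""
    if x_max <= x_min:
        raise RangeError(f"x_max must exceed x_min ({x_min} >= {x_max})")
    return min(1.0, max(0.0, (x - x_min) / (x_max - x_min)))


def basket_score(basket: Basket, ctx: Context24h,
                 ranges: Mapping[str, FeatureRange]) -> float:
    """Weighted sum of range-scaled context features (deterministic)."""
    score = 0.0
    for feature, w in basket.weights.items():
        if feature not in ranges:
            raise RecommenderConfigError(f"no range defined for feature {feature!r}")
        if feature not in ctx.features:
            raise RecommenderConfigError(f"no context value for feature {feature!r}")
        r = ranges[feature]
        score += w * scale_to_range(ctx.features[feature], r.x_min, r.x_max)
    return score


def intervention_score(state: InterventionState, rng_draw: float) -> float:
    """Preference score; the caller injects the uniform draw for the bonus."""
    score = (RATING_WEIGHT * state.mean_rating / 5.0
             - CANCEL_WEIGHT * state.cancellation_rate)
    if rng_draw <= CHANCE_BONUS_P:
        score += CHANCE_BONUS
    return score


def block_time(last_rating: int) -> float:
    """Post-execution block duration in hours, decreasing in the rating."""
    if last_rating not in (1, 2, 3, 4, 5):
        raise ValueError(f"rating must be in 1..5, got {last_rating}")
    return float(BLOCK_HOURS_PER_STAR * (6 - last_rating))


def record_execution(state: InterventionState, rating: int, now: int) -> None:
    """Register a completed intervention and advance its block timer."""
    state.ratings.append(int(rating))
    state.executions += 1
    state.blocked_until = now + round(block_time(rating) * MS_PER_HOUR)


def record_cancellation(state: InterventionState) -> None:
    state.cancellations += 1


def personalize_ranges(day_values: Mapping[str, Sequence[float]],
                       count_features: frozenset[str] | None = None,
                       min_width: float = 1.0,
                       source: str = "personalized") -> dict[str, FeatureRange]:
    """Phase-2 ranges: per feature mean +/- 2 sd over the last week's days.

    Count-like features are clipped below at 0; a degenerate (zero-variance)
    range is widened symmetrically to ``min_width``.
    """
    if count_features is None:
        count_features = frozenset(day_values)
    out: dict[str, FeatureRange] = {}
    for feature, vals in day_values.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2:
            raise RangeError(f"{feature}: need >= 2 valid days to personalize")
        mu, sd = float(np.mean(vals)), float(np.std(vals))
        lo, hi = mu - 2.0 * sd, mu + 2.0 * sd
        if hi - lo < min_width:
            lo, hi = mu - min_width / 2.0, mu + min_width / 2.0
        if feature in count_features:
            lo = max(0.0, lo)
            if hi <= lo:
                hi = lo + min_width
        out[feature] = FeatureRange(feature, lo, hi, source=source)
    return out


# ---------------------------------------------------------------------------
# recommendation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedIntervention:
    intervention_id: str
    score: float


@dataclass(frozen=True)
class BasketRecommendation:
    basket_id: str
    domain: str
    score: float
    display_radius: float              # monotone in basket score
    interventions: tuple[RankedIntervention, ...]
    all_blocked: bool = False


@dataclass(frozen=True)
class Recommendation:
    t: int
    baskets: tuple[BasketRecommendation, ...]


def evaluation_epoch(t: int, tz_offset_hours: float = 0.0) -> int:
    """Index of the 6-hour evaluation epoch containing t (boundaries at
    local 00/06/12/18)."""
    local = t + round(tz_offset_hours * MS_PER_HOUR)
    return local // (EVAL_PERIOD_HOURS * MS_PER_HOUR)


def _display_radius(score: float, lo: float, hi: float,
                    r_min: float = 0.5, r_max: float = 1.0) -> float:
    if hi <= lo:
        return r_max
    return r_min + (r_max - r_min) * (score - lo) / (hi - lo)


def recommend(ctx: Context24h, baskets: Sequence[Basket],
              ranges: Mapping[str, FeatureRange],
              rng: np.random.Generator,
              top_k_baskets: int = TOP_K_BASKETS,
              top_k_interventions: int = TOP_K_INTERVENTIONS) -> Recommendation:
    """Rank baskets by score and fill each with its top eligible interventions.

    Ties between basket scores break on basket id; interventions that fail an
    eligibility rule or are still block-timed are excluded.  A basket whose
    interventions are all excluded is presented empty-flagged.  With the rng
    fixed the output is deterministic.
    """
    if not baskets:
        raise RecommenderConfigError("need at least one basket")
    scored = sorted(((basket_score(b, ctx, ranges), b) for b in baskets),
                    key=lambda sb: (-sb[0], sb[1].basket_id))
    shown = scored[:top_k_baskets]
    scores = [s for s, _ in scored]
    lo, hi = min(scores), max(scores)

    out = []
    for score, basket in shown:
        eligible = [iv for iv in basket.interventions
                    if iv.rule.allows(ctx.at_home, ctx.slot) and not iv.is_blocked(ctx.t)]
        ranked = sorted(
            (RankedIntervention(iv.intervention_id,
                                intervention_score(iv, float(rng.random())))
             for iv in eligible),
            key=lambda ri: (-ri.score, ri.intervention_id))[:top_k_interventions]
        out.append(BasketRecommendation(
            basket_id=basket.basket_id, domain=basket.domain, score=score,
            display_radius=_display_radius(score, lo, hi),
            interventions=tuple(ranked),
            all_blocked=bool(basket.interventions) and not eligible))
    return Recommendation(t=ctx.t, baskets=tuple(out))


# ---------------------------------------------------------------------------
# default catalog + persistence
# ---------------------------------------------------------------------------

#: Population ranges for the features the recommender weights, spanning the
#: published population-assumption anchors.
DEFAULT_RANGES: dict[str, FeatureRange] = {
    r.feature: r for r in (
        FeatureRange("time_at_home_min", 7 * 60.0, 14 * 60.0),
        FeatureRange("calls_total", 0.0, 6.0),
        FeatureRange("walking_min", 30.0, 300.0),
        FeatureRange("sms_total", 0.0, 10.0),
        FeatureRange("cal_total", 0.0, 4.0),
        FeatureRange("avg_call_duration_s", 0.0, 600.0),
        FeatureRange("phone_use_min", 30.0, 360.0),
    )
}


def default_catalog() -> list[Basket]:
    """A small hand-set basket catalog.

    Weights are signed so that an under-expressed healthy behavior raises the
    score of the basket that trains it: e.g. little walking in the last 24 h
    pushes the physical basket up.
    """
    return [
        Basket("b_physical", "physical",
               weights={"walking_min": -1.0, "time_at_home_min": 0.5},
               interventions=[
                   InterventionState("iv_walk_10min", "b_physical", "activity_tracker",
                                     duration_min=10.0),
                   InterventionState("iv_morning_stretch", "b_physical", "button",
                                     duration_min=3.0,
                                     rule=EligibilityRule(slots=("morning",))),
                   InterventionState("iv_stair_climb", "b_physical", "countdown",
                                     duration_min=5.0),
                   InterventionState("iv_posture_hold", "b_physical", "countdown",
                                     duration_min=2.0),
               ]),
        Basket("b_social", "social",
               weights={"calls_total": -0.8, "sms_total": -0.4,
                        "time_at_home_min": 0.4},
               interventions=[
                   InterventionState("iv_call_friend", "b_social", "checkbox",
                                     duration_min=10.0),
                   InterventionState("iv_coffee_invite", "b_social", "checkbox",
                                     duration_min=5.0,
                                     rule=EligibilityRule(slots=("afternoon", "evening"))),
                   InterventionState("iv_movies_popcorn", "b_social", "checkbox",
                                     duration_min=5.0,
                                     rule=EligibilityRule(slots=("evening",))),
                   InterventionState("iv_praise_message", "b_social", "checkbox",
                                     duration_min=2.0),
               ]),
        Basket("b_mindfulness", "mindfulness",
               weights={"phone_use_min": 0.6, "cal_total": 0.4},
               interventions=[
                   InterventionState("iv_awareness_intro", "b_mindfulness", "multitext",
                                     duration_min=8.0),
                   InterventionState("iv_awareness_quiz", "b_mindfulness", "quiz",
                                     duration_min=5.0),
                   InterventionState("iv_mirror_smile", "b_mindfulness", "mirror",
                                     duration_min=1.0),
                   InterventionState("iv_praise_yourself", "b_mindfulness", "checkbox",
                                     duration_min=2.0),
               ]),
        Basket("b_relaxation", "relaxation",
               weights={"cal_total": 0.7, "phone_use_min": 0.3},
               interventions=[
                   # lie-down exercise: at home, morning or evening only
                   InterventionState("iv_liedown_breathing", "b_relaxation", "audio",
                                     duration_min=10.0,
                                     rule=EligibilityRule(locations=("home",),
                                                          slots=("morning", "evening"))),
                   InterventionState("iv_breathing_audio", "b_relaxation", "audio",
                                     duration_min=6.0),
                   InterventionState("iv_muscle_release", "b_relaxation", "countdown",
                                     duration_min=4.0),
                   InterventionState("iv_muse_chair", "b_relaxation", "multitext",
                                     duration_min=6.0),
               ]),
    ]


# -- JSON persistence of recommender state -----------------------------------

def catalog_to_dict(baskets: Sequence[Basket]) -> dict:
    return {"baskets": [
        {"basket_id": b.basket_id, "domain": b.domain, "weights": b.weights,
         "interventions": [
             {"intervention_id": iv.intervention_id, "basket_id": iv.basket_id,
              "type": iv.type, "duration_min": iv.duration_min,
              "locations": list(iv.rule.locations) if iv.rule.locations else None,
              "slots": list(iv.rule.slots) if iv.rule.slots else None,
              "ratings": iv.ratings, "cancellations": iv.cancellations,
              "executions": iv.executions, "blocked_until": iv.blocked_until}
             for iv in b.interventions]}
        for b in baskets]}


def catalog_from_dict(doc: dict) -> list[Basket]:
    baskets = []
    for b in doc["baskets"]:
        ivs = [InterventionState(
            intervention_id=d["intervention_id"], basket_id=d["basket_id"],
            type=d.get("type", "checkbox"), duration_min=d.get("duration_min", 5.0),
            rule=EligibilityRule(
                locations=tuple(d["locations"]) if d.get("locations") else None,
                slots=tuple(d["slots"]) if d.get("slots") else None),
            ratings=list(d.get("ratings", [])),
            cancellations=d.get("cancellations", 0),
            executions=d.get("executions", 0),
            blocked_until=d.get("blocked_until"))
            for d in b.get("interventions", [])]
        baskets.append(Basket(b["basket_id"], b["domain"], dict(b["weights"]), ivs))
    return baskets


def recommendation_to_dict(rec: Recommendation) -> dict:
    return asdict(rec)
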