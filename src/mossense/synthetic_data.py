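"""Multi-week subject-stream simulator driven by a latent severity trajectory.

Behavior means vary with severity in the directions assumed for a depressed
population: higher severity means more time at home, fewer calls and texts,
less walking, more phone use.  The severity-to-behavior map is a linear
interpolation between configurable anchor pairs (mean at severity 0, mean at
severity 27); the default anchors bracket the published population
assumptions (time at home spanning below 7 h/day up to above 14 h/day, calls
spanning above 6/day down to 0, walking spanning above 300 min/day down to
below 30).

Everything is generated from ``numpy.random.Generator`` streams spawned off
a single seed, so identical configurations are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from typing import Sequence

import numpy as np

from .sensor_model import (
    MS_PER_DAY,
    MS_PER_HOUR,
    MS_PER_MIN,
    MS_PER_SEC,
    PHQ9_MAX,
    AppSession,
    ActivityWindow,
    CalendarEvent,
    CommEvent,
    GpsFix,
    PhoneUseInterval,
    Phq9Record,
    SubjectStream,
    WifiScan,
    day_start_ms,
    local_date,
    slot_of,
)

SEVERITY_MAX = float(PHQ9_MAX)

#: (mean at severity 0, mean at severity 27) per behavioral quantity.
DEFAULT_ANCHORS: dict[str, tuple[float, float]] = {
    "time_at_home_min": (360.0, 900.0),   # 6 h -> 15 h per day
    "walking_min": (320.0, 20.0),         # > 300 min -> < 30 min
    "calls_per_day": (7.0, 0.0),          # > 6 -> 0
    "texts_per_day": (10.0, 1.0),
    "avg_call_duration_s": (300.0, 60.0),
    "loc_spread_deg": (0.05, 0.004),      # away-from-home scatter radius
    "phone_use_min": (120.0, 320.0),
    "cal_events_per_day": (3.0, 0.5),
    "sessions_per_day": (1.5, 1.5),
}

#: Fraction of the anchor span used as the day-level Gaussian noise sd at
#: noise_level=1.
_NOISE_SD_FRACTION = 0.08

SLOTS_PER_DAY = 96          # 15-min WiFi/GPS cadence
WINDOWS_PER_DAY = 720       # 2-min activity windows
NIGHT_SLOTS = 20            # [00:00, 05:00) at 15-min cadence

DEFAULT_ENROLLMENT_MS = day_start_ms(date(2015, 1, 5))  # trial-era Monday


class SimConfigError(ValueError):
    """A simulation profile or cohort configuration is invalid."""


@dataclass
class SimProfile:
    """Generative profile for one subject."""

    subject_id: str = "S000"
    severity_trajectory: Sequence[float] = (10.0,)   # one value per 14-day epoch
    anchors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ANCHORS))
    noise_level: float = 1.0        # 0 disables day-level behavior noise
    phq9_noise_sd: float = 2.0      # discretized Gaussian on observed scores
    effect_scale: float = 1.0       # scales anchor spread about its midpoint
    seed: int = 0
    tz_offset_hours: float = 0.0
    enrollment: int = DEFAULT_ENROLLMENT_MS
    home_lat: float = 47.3769
    home_lon: float = 8.5417
    n_home_bssids: int = 2
    guarantee_home_nights: bool = True  # keep [00:00,05:00) at home every day

    def validate(self) -> "SimProfile":
        if not self.severity_trajectory:
            raise SimConfigError("severity trajectory must have >= 1 epoch")
        for s in self.severity_trajectory:
            if not np.isfinite(s) or not 0.0 <= s <= SEVERITY_MAX:
                raise SimConfigError(f"severity {s} outside [0, {SEVERITY_MAX}]")
        for name, (lo, hi) in self.anchors.items():
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise SimConfigError(f"non-finite anchor for {name}")
        if not np.isfinite(self.noise_level) or self.noise_level < 0:
            raise SimConfigError("noise_level must be finite and >= 0")
        if not np.isfinite(self.effect_scale):
            raise SimConfigError("effect_scale must be finite")
        return self


@dataclass
class SimCohortConfig:
    n_subjects: int = 10
    weeks: int = 4                       # per subject, before dropout; even
    dropout_hazard: float = 0.0          # applied after each completed 2-week epoch
    frac_depressed_baseline: float = 0.5  # baseline PHQ-9 >= 11
    seed: int = 0
    noise_level: float = 1.0
    phq9_noise_sd: float = 2.0
    effect_scale: float = 1.0
    anchors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ANCHORS))

    def validate(self) -> "SimCohortConfig":
        if self.n_subjects < 1:
            raise SimConfigError("n_subjects must be >= 1")
        if self.weeks < 2 or self.weeks % 2:
            raise SimConfigError("weeks must be an even number >= 2")
        if not 0.0 <= self.dropout_hazard <= 1.0:
            raise SimConfigError("dropout_hazard must be in [0, 1]")
        if not 0.0 <= self.frac_depressed_baseline <= 1.0:
            raise SimConfigError("frac_depressed_baseline must be in [0, 1]")
        return self

    @property
    def epochs(self) -> int:
        return self.weeks // 2


@dataclass
class SubjectTruth:
    """Ground truth emitted alongside a simulated stream, for oracle tests."""
    subject_id: str
    severities: list[float]
    home_bssids: list[str]
    epochs_completed: int
    daily: dict[str, dict[str, float]]   # ISO date -> behavioral targets
    n_qualifying_sessions: int
    phq9_scores: list[int]


def expected_daily_behavior(profile: SimProfile, severity: float) -> dict[str, float]:
    """Noise-free daily behavior means implied by a severity value.

    This is the generator-mean surface that the monotone-coupling property
    is asserted on.
    """
    frac = float(np.clip(severity / SEVERITY_MAX, 0.0, 1.0))
    out = {}
    for name, (lo, hi) in profile.anchors.items():
        mid = 0.5 * (lo + hi)
        lo_s = mid + (lo - mid) * profile.effect_scale
        hi_s = mid + (hi - mid) * profile.effect_scale
        out[name] = max(0.0, lo_s + (hi_s - lo_s) * frac)
    return out


def _count(rng: np.random.Generator, mean: float, noise_level: float) -> int:
    """Integer event count: deterministic rounding when noise-free, Poisson otherwise."""
    if noise_level == 0:
        return int(round(mean))
    return int(rng.poisson(mean))


def _noisy(rng: np.random.Generator, mean: float, span: float, noise_level: float) -> float:
    if noise_level == 0:
        return mean
    return max(0.0, mean + rng.normal(0.0, _NOISE_SD_FRACTION * abs(span) * noise_level))


def _home_slot_order() -> list[int]:
    """Slot indices in the order they are claimed for at-home time: the
    night block first, then evening backwards, then morning onwards."""
    order = list(range(NIGHT_SLOTS))
    order += list(range(SLOTS_PER_DAY - 1, NIGHT_SLOTS - 1, -1))
    return order


_HOME_ORDER = _home_slot_order()


def simulate_subject_with_truth(profile: SimProfile) -> tuple[SubjectStream, SubjectTruth]:
    profile.validate()
    rng = np.random.default_rng(np.random.SeedSequence(profile.seed))
    tz = profile.tz_offset_hours

    home_bssids = [f"home_{profile.subject_id}_{i}" for i in range(profile.n_home_bssids)]
    city_pool = [f"ap_{i:03d}" for i in range(60)]
    contact_pool = [f"c{i:02d}" for i in range(12)]

    stream = SubjectStream(subject_id=profile.subject_id, enrollment=profile.enrollment,
                           tz_offset_hours=tz)
    n_epochs = len(profile.severity_trajectory)
    n_days = 14 * n_epochs
    d0 = local_date(profile.enrollment, tz)

    daily_truth: dict[str, dict[str, float]] = {}
    n_qualifying = 0

    for k in range(n_days):
        day = d0 + timedelta(days=k)
        start = day_start_ms(day, tz)
        severity = float(profile.severity_trajectory[k // 14])
        means = expected_daily_behavior(profile, severity)

        home_min = _noisy(rng, means["time_at_home_min"],
                          np.ptp(profile.anchors["time_at_home_min"]), profile.noise_level)
        walk_min = _noisy(rng, means["walking_min"],
                          np.ptp(profile.anchors["walking_min"]), profile.noise_level)
        spread = max(1e-4, means["loc_spread_deg"])
        phone_min = _noisy(rng, means["phone_use_min"],
                           np.ptp(profile.anchors["phone_use_min"]), profile.noise_level)

        n_home = int(round(home_min / 15.0))
        if profile.guarantee_home_nights:
            n_home = max(n_home, NIGHT_SLOTS)
        n_home = min(n_home, SLOTS_PER_DAY)
        home_slots = set(_HOME_ORDER[:n_home])

        # 15-min cadence GPS + WiFi
        for slot in range(SLOTS_PER_DAY):
            t = start + slot * 15 * MS_PER_MIN
            if slot in home_slots:
                lat = profile.home_lat + rng.normal(0.0, 1e-5)
                lon = profile.home_lon + rng.normal(0.0, 1e-5)
                bssids = frozenset(home_bssids)
                if profile.noise_level > 0 and rng.random() < 0.3:
                    bssids |= frozenset(rng.choice(city_pool, size=1))
            else:
                ang = rng.uniform(0.0, 2.0 * np.pi)
                r = spread * np.sqrt(rng.uniform(0.2, 1.0))
                lat = profile.home_lat + r * np.sin(ang)
                lon = profile.home_lon + r * np.cos(ang)
                n_ap = int(rng.integers(1, 4))
                bssids = frozenset(rng.choice(city_pool, size=n_ap, replace=False))
            stream.gps.append(GpsFix(t, float(np.clip(lat, -90, 90)),
                                     float(np.clip(lon, -180, 180))))
            stream.wifi.append(WifiScan(t, bssids))

        # 2-min activity windows covering the whole day
        n_walk = min(int(round(walk_min / 2.0)), WINDOWS_PER_DAY)
        day_idx = np.arange(150, WINDOWS_PER_DAY)  # walking happens after 05:00
        walk_windows = set(rng.choice(day_idx, size=min(n_walk, day_idx.size),
                                      replace=False).tolist())
        if n_walk > day_idx.size:   # extreme profiles spill into the night
            walk_windows |= set(range(n_walk - day_idx.size))
        for w in range(WINDOWS_PER_DAY):
            walking = w in walk_windows
            sd = rng.uniform(1.6, 3.0) if walking else rng.uniform(0.02, 1.2)
            stream.windows.append(ActivityWindow(start=start + w * 120 * MS_PER_SEC,
                                                 stdev_norm=float(sd), is_walking=walking))

        # communication
        n_calls = _count(rng, means["calls_per_day"], profile.noise_level)
        n_sms = _count(rng, means["texts_per_day"], profile.noise_level)
        comm_today: list[CommEvent] = []
        for i in range(n_calls):
            t = start + int(rng.integers(8, 22) * MS_PER_HOUR) + int(rng.integers(0, MS_PER_HOUR))
            dur = (means["avg_call_duration_s"] if profile.noise_level == 0
                   else float(rng.exponential(max(means["avg_call_duration_s"], 1.0))))
            comm_today.append(CommEvent(t, "call", "in" if i % 2 else "out",
                                        str(rng.choice(contact_pool)), duration_s=dur))
        for i in range(n_sms):
            t = start + int(rng.integers(7, 23) * MS_PER_HOUR) + int(rng.integers(0, MS_PER_HOUR))
            comm_today.append(CommEvent(t, "sms", "in" if i % 2 else "out",
                                        str(rng.choice(contact_pool))))
        stream.comm.extend(sorted(comm_today, key=lambda e: e.t))

        # calendar events, spread over the three slots
        n_cal = _count(rng, means["cal_events_per_day"], profile.noise_level)
        slot_hours = {"morning": (5, 12), "afternoon": (12, 18), "evening": (18, 24)}
        cal_today = []
        for _ in range(n_cal):
            slot_name = str(rng.choice(["morning", "afternoon", "evening"]))
            lo, hi = slot_hours[slot_name]
            t = start + int(rng.uniform(lo, hi) * MS_PER_HOUR)
            cal_today.append(CalendarEvent(t, slot_of(t, tz)))
        stream.calendar.extend(sorted(cal_today, key=lambda e: e.t))

        # phone use: four unlocked intervals across waking hours
        remaining = phone_min
        for h in (8, 12, 17, 21):
            part = min(remaining, phone_min / 4.0)
            if part <= 0:
                break
            t0 = start + h * MS_PER_HOUR
            stream.phone_use.append(PhoneUseInterval(
                t0, t0 + max(1, int(part * MS_PER_MIN)), in_moss_app=0.0))
            remaining -= part

        # app sessions
        n_sess = _count(rng, means["sessions_per_day"], profile.noise_level)
        for _ in range(n_sess):
            t = start + int(rng.integers(8, 23) * MS_PER_HOUR)
            n_iv = int(rng.integers(0, 3))
            stream.sessions.append(AppSession(t, n_iv))
            n_qualifying += int(n_iv >= 1)
        stream.sessions.sort(key=lambda s: s.t)

        daily_truth[day.isoformat()] = {
            "severity": severity,
            "time_at_home_min": 15.0 * n_home,
            "walking_min": 2.0 * len(walk_windows),
            "calls_total": float(n_calls),
            "sms_total": float(n_sms),
            "phone_use_min": float(phone_min),
        }

    # biweekly PHQ-9: baseline plus one record at the end of each epoch
    scores: list[int] = []
    for e in range(n_epochs + 1):
        sev = profile.severity_trajectory[0] if e == 0 else profile.severity_trajectory[e - 1]
        noise = 0.0 if profile.phq9_noise_sd == 0 else rng.normal(0.0, profile.phq9_noise_sd)
        score = int(np.clip(round(sev + noise), 0, PHQ9_MAX))
        t = profile.enrollment + e * 14 * MS_PER_DAY
        stream.phq9.append(Phq9Record(t, score))
        scores.append(score)

    stream.validate()
    truth = SubjectTruth(subject_id=profile.subject_id,
                         severities=[float(s) for s in profile.severity_trajectory],
                         home_bssids=home_bssids,
                         epochs_completed=n_epochs,
                         daily=daily_truth,
                         n_qualifying_sessions=n_qualifying,
                         phq9_scores=scores)
    return stream, truth


def simulate_subject(profile: SimProfile) -> SubjectStream:
    """Simulate one subject; see :func:`simulate_subject_with_truth`."""
    return simulate_subject_with_truth(profile)[0]


def simulate_cohort(config: SimCohortConfig) -> list[SubjectStream]:
    return [st for st, _ in simulate_cohort_with_truth(config)]


def simulate_cohort_with_truth(
        config: SimCohortConfig) -> list[tuple[SubjectStream, SubjectTruth]]:
    """Simulate a cohort with epoch-wise dropout.

    After each completed 2-week epoch a subject drops out with probability
    ``dropout_hazard``; every subject completes at least the baseline epoch.
    A subject is still enrolled at week ``2k`` iff it survived ``k`` hazard
    draws.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_subjects + 1)
    meta_rng = np.random.default_rng(child_seeds[0])

    n_dep = int(round(config.frac_depressed_baseline * config.n_subjects))
    depressed = np.zeros(config.n_subjects, dtype=bool)
    depressed[meta_rng.permutation(config.n_subjects)[:n_dep]] = True

    out = []
    for i in range(config.n_subjects):
        sub_rng = np.random.default_rng(child_seeds[i + 1])
        base = (float(sub_rng.integers(11, 25)) if depressed[i]
                else float(sub_rng.integers(0, 11)))
        epochs = 1
        while epochs < config.epochs and sub_rng.random() >= config.dropout_hazard:
            epochs += 1
        traj = [base]
        for _ in range(1, epochs):
            traj.append(float(np.clip(traj[-1] + sub_rng.normal(0.0, 1.5), 0.0, SEVERITY_MAX)))
        profile = SimProfile(subject_id=f"S{i:03d}",
                             severity_trajectory=traj,
                             anchors=dict(config.anchors),
                             noise_level=config.noise_level,
                             phq9_noise_sd=config.phq9_noise_sd,
                             effect_scale=config.effect_scale,
                             seed=int(sub_rng.integers(0, 2**31 - 1)))
        stream, truth = simulate_subject_with_truth(profile)
        out.append((stream, truth))
    return out


def truth_to_json(truths: list[SubjectTruth]) -> str:
    return json.dumps({t.subject_id: asdict(t) for t in truths}, indent=1)
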