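"""Base behavioral-proxy features computed from a subject's event streams.

Implements the per-window activity statistic (standard deviation of the
gravity-corrected acceleration-norm signal), intensity-threshold walking
classification, WiFi-fingerprint home detection, GPS mobility metrics
including the log location variance, and the per-calendar-day feature table
every downstream stage consumes.

Missing-data semantics: sampled sensors (accelerometer, GPS, WiFi) that
produced no events on a day yield masked values for that day; eventful
streams (communication, calendar, phone use) are masked only when the
subject has no events of that kind at all, since an empty day is a real
zero there.  Average call duration is additionally masked on days with no
calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import numpy as np

from .sensor_model import (
    MS_PER_DAY,
    MS_PER_MIN,
    AccelSample,
    GpsFix,
    SubjectStream,
    WifiScan,
    day_start_ms,
    events_in,
    local_date,
    local_hour,
)

GRAVITY_MS2 = 9.81
WALKING_THRESHOLD = 1.5          # stdev_norm at/above which a window is walking
EARTH_RADIUS_M = 6_371_000.0
LOCVAR_FLOOR_DEG2 = 1e-12        # zero-variance days are floored, not errors


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class HomeFingerprint:
    """The BSSID set identifying a subject's home location."""
    bssids: frozenset[str]
    learned_at: int
    confirmed: bool = True

    def __post_init__(self):
        if self.confirmed and not self.bssids:
            raise ValueError("a confirmed home fingerprint must be non-empty")


@dataclass(frozen=True)
class FeatureConfig:
    """Tunables for feature extraction; defaults follow the published values
    where one is stated and documented conventions otherwise."""
    walking_threshold: float = WALKING_THRESHOLD
    night_hours: tuple[float, float] = (0.0, 5.0)    # local home-learning window
    jaccard_threshold: float = 0.5                   # "reasonable overlap" of nightly sets
    night_presence_min: float = 0.5                  # fraction of night scans a BSSID
                                                     # must appear in to enter the set
    home_match_rule: str = "any"                     # {"any", "fraction"}
    home_match_min_fraction: float = 0.5
    scan_interval_min: float = 15.0
    window_min: float = 2.0
    locvar_floor: float = LOCVAR_FLOOR_DEG2
    gravity: float = GRAVITY_MS2


# ---------------------------------------------------------------------------
# accelerometer
# ---------------------------------------------------------------------------

def activity_stdev(samples: Sequence[AccelSample], gravity: float = GRAVITY_MS2) -> float:
    """Standard deviation of per-sample acceleration norms minus gravity.

    The norm makes the statistic invariant to the orientation of the axis
    frame; subtracting the gravity constant centres a resting signal near 0
    (the constant cancels inside the standard deviation).
    """
    if len(samples) < 2:
        raise InsufficientDataError(
            f"activity window needs >= 2 samples, got {len(samples)}")
    a = np.array([(s.ax, s.ay, s.az) for s in samples], dtype=float)
    norms = np.sqrt((a * a).sum(axis=1)) - gravity
    return float(np.std(norms))


def classify_walking(stdev_norm: float, threshold: float = WALKING_THRESHOLD) -> bool:
    """Intensity-threshold walking test; the boundary is inclusive."""
    if stdev_norm < 0:
        raise ValueError(f"stdev_norm must be >= 0, got {stdev_norm}")
    return stdev_norm >= threshold


# ---------------------------------------------------------------------------
# WiFi home detection
# ---------------------------------------------------------------------------

def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def nightly_bssid_sets(scans: Iterable[WifiScan], tz_offset_hours: float = 0.0,
                       night_hours: tuple[float, float] = (0.0, 5.0),
                       presence_min: float = 0.5) -> dict[date, frozenset[str]]:
    """Per-night BSSID fingerprints keyed by local date.

    A BSSID enters a night's set only when it appears in at least
    ``presence_min`` of that night's scans, so hotspots caught in a single
    stray scan do not dilute the fingerprint.
    """
    lo, hi = night_hours
    counts: dict[date, dict[str, int]] = {}
    totals: dict[date, int] = {}
    for s in scans:
        if lo <= local_hour(s.t, tz_offset_hours) < hi:
            d = local_date(s.t, tz_offset_hours)
            totals[d] = totals.get(d, 0) + 1
            per = counts.setdefault(d, {})
            for b in s.bssids:
                per[b] = per.get(b, 0) + 1
    out: dict[date, frozenset[str]] = {}
    for d, per in counts.items():
        keep = frozenset(b for b, c in per.items() if c >= presence_min * totals[d])
        if keep:
            out[d] = keep
    return out


def learn_home(scans: Sequence[WifiScan], tz_offset_hours: float = 0.0,
               config: FeatureConfig = FeatureConfig()) -> HomeFingerprint | None:
    """Learn a home fingerprint from the first 3 consecutive nights whose
    BSSID sets overlap pairwise by at least the Jaccard threshold.

    Returns the intersection of the three nightly sets, or ``None`` when no
    qualifying triple exists (absence is a valid outcome; a deployed app
    would fall back to asking the user).
    """
    nights = nightly_bssid_sets(scans, tz_offset_hours, config.night_hours,
                                config.night_presence_min)
    days = sorted(nights)
    for d in days:
        d1, d2 = d.fromordinal(d.toordinal() + 1), d.fromordinal(d.toordinal() + 2)
        if d1 not in nights or d2 not in nights:
            continue
        sets = (nights[d], nights[d1], nights[d2])
        if all(_jaccard(a, b) >= config.jaccard_threshold
               for a, b in ((sets[0], sets[1]), (sets[0], sets[2]), (sets[1], sets[2]))):
            fp = sets[0] & sets[1] & sets[2]
            if fp:
                learned_at = day_start_ms(d2, tz_offset_hours) + MS_PER_DAY
                return HomeFingerprint(bssids=fp, learned_at=learned_at, confirmed=True)
    return None


def scan_matches_home(scan: WifiScan, home: HomeFingerprint,
                      config: FeatureConfig = FeatureConfig()) -> bool:
    if config.home_match_rule == "any":
        return bool(scan.bssids & home.bssids)
    if config.home_match_rule == "fraction":
        if not home.bssids:
            return False
        return len(scan.bssids & home.bssids) / len(home.bssids) >= config.home_match_min_fraction
    raise ValueError(f"unknown home_match_rule {config.home_match_rule!r}")


# ---------------------------------------------------------------------------
# GPS mobility
# ---------------------------------------------------------------------------

def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float,
                radius_m: float = EARTH_RADIUS_M) -> float:
    """Great-circle distance on a spherical Earth."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2.0) ** 2
    return 2.0 * radius_m * math.asin(min(1.0, math.sqrt(a)))


def gps_metrics(fixes: Sequence[GpsFix],
                locvar_floor: float = LOCVAR_FLOOR_DEG2) -> tuple[float, float, float]:
    """(max pairwise distance m, total consecutive distance m, log location variance).

    The log location variance is the natural log of the sum of the population
    variances of raw latitude and longitude in degrees squared; it requires
    >= 2 fixes and is NaN otherwise.  A day with zero coordinate spread is
    floored at ``locvar_floor`` before the log rather than erroring.
    """
    if len(fixes) < 1:
        raise InsufficientDataError("gps_metrics needs >= 1 fix")
    lat = np.array([f.lat for f in fixes])
    lon = np.array([f.lon for f in fixes])

    total = sum(haversine_m(lat[i], lon[i], lat[i + 1], lon[i + 1])
                for i in range(len(fixes) - 1))

    # max pairwise distance via chord length on the unit sphere (vectorised)
    phi, lam = np.radians(lat), np.radians(lon)
    xyz = np.stack([np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)], axis=1)
    if len(fixes) == 1:
        max_d = 0.0
    else:
        chord2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(-1)
        half = np.sqrt(np.clip(chord2.max(), 0.0, 4.0)) / 2.0
        max_d = 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, half))

    if len(fixes) >= 2:
        loc_var = float(np.log(max(np.var(lat) + np.var(lon), locvar_floor)))
    else:
        loc_var = float("nan")
    return float(max_d), float(total), loc_var


# ---------------------------------------------------------------------------
# per-day feature table
# ---------------------------------------------------------------------------

#: The 18 directly-measured day features, in canonical order.
BASE_DAY_FIELDS = (
    "general_activity", "walking_min", "time_at_home_min", "phone_use_min",
    "max_dist_m", "total_dist_m", "loc_var", "n_unique_wifi",
    "sms_in", "sms_out", "sms_unique_contacts",
    "calls_in", "calls_out", "calls_unique_contacts", "avg_call_duration_s",
    "cal_morning", "cal_afternoon", "cal_evening",
)


@dataclass(frozen=True)
class DayFeatures:
    """Base behavioral features of one subject-local calendar day.

    ``missing`` names the fields whose sensor produced no usable data that
    day; masked fields hold 0.0 placeholders and must be treated as absent.
    """
    day: date
    general_activity: float = 0.0
    walking_min: float = 0.0
    time_at_home_min: float = 0.0
    phone_use_min: float = 0.0
    max_dist_m: float = 0.0
    total_dist_m: float = 0.0
    loc_var: float = 0.0
    n_unique_wifi: float = 0.0
    sms_in: float = 0.0
    sms_out: float = 0.0
    sms_unique_contacts: float = 0.0
    calls_in: float = 0.0
    calls_out: float = 0.0
    calls_unique_contacts: float = 0.0
    avg_call_duration_s: float = 0.0
    cal_morning: float = 0.0
    cal_afternoon: float = 0.0
    cal_evening: float = 0.0
    n_gps_fixes: float = 0.0       # bookkeeping for per-fix normalisation
    missing: frozenset[str] = frozenset()

    def __post_init__(self):
        for name in ("walking_min", "time_at_home_min", "phone_use_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1440.0 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 1440]")
        for name in BASE_DAY_FIELDS:
            if name == "loc_var":
                continue
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def value(self, name: str) -> float:
        return getattr(self, name)

    def is_missing(self, name: str) -> bool:
        return name in self.missing


def daily_base_features(stream: SubjectStream, day: date,
                        home: HomeFingerprint | None,
                        config: FeatureConfig = FeatureConfig()) -> DayFeatures:
    """Populate every base feature from one local calendar day of events."""
    tz = stream.tz_offset_hours
    lo = day_start_ms(day, tz)
    hi = lo + MS_PER_DAY
    missing: set[str] = set()

    # accelerometer windows
    windows = events_in(stream.windows, lo, hi)
    if windows:
        general = float(np.mean([w.stdev_norm for w in windows]))
        walking = config.window_min * sum(
            classify_walking(w.stdev_norm, config.walking_threshold) for w in windows)
    else:
        general = walking = 0.0
        missing.update(("general_activity", "walking_min"))

    # WiFi
    scans = events_in(stream.wifi, lo, hi)
    if scans:
        n_unique = float(len(frozenset().union(*(s.bssids for s in scans))))
        if home is not None:
            at_home = config.scan_interval_min * sum(
                scan_matches_home(s, home, config) for s in scans)
        else:
            at_home = 0.0
            missing.add("time_at_home_min")   # no fingerprint: flagged, not zero
    else:
        n_unique = at_home = 0.0
        missing.update(("n_unique_wifi", "time_at_home_min"))

    # GPS
    fixes = events_in(stream.gps, lo, hi)
    if fixes:
        max_d, total_d, loc_var = gps_metrics(fixes, config.locvar_floor)
        if math.isnan(loc_var):
            loc_var = 0.0
            missing.add("loc_var")
    else:
        max_d = total_d = loc_var = 0.0
        missing.update(("max_dist_m", "total_dist_m", "loc_var"))

    # phone use: intervals clipped to the day, in-app time prorated out
    if stream.phone_use:
        used_ms = 0.0
        for p in stream.phone_use:
            ov = min(p.t_lock, hi) - max(p.t_unlock, lo)
            if ov <= 0:
                continue
            frac = ov / (p.t_lock - p.t_unlock)
            used_ms += ov - frac * p.in_moss_app * 1000.0
        phone_min = max(0.0, used_ms / MS_PER_MIN)
    else:
        phone_min = 0.0
        missing.add("phone_use_min")

    # communication
    if stream.comm:
        evs = events_in(stream.comm, lo, hi)
        sms = [e for e in evs if e.kind == "sms"]
        calls = [e for e in evs if e.kind == "call"]
        sms_in = float(sum(e.direction == "in" for e in sms))
        sms_out = float(len(sms) - sms_in)
        calls_in = float(sum(e.direction == "in" for e in calls))
        calls_out = float(len(calls) - calls_in)
        sms_uc = float(len({e.contact for e in sms}))
        calls_uc = float(len({e.contact for e in calls}))
        if calls:
            avg_dur = float(np.mean([e.duration_s for e in calls]))
        else:
            avg_dur = 0.0
            missing.add("avg_call_duration_s")
    else:
        sms_in = sms_out = calls_in = calls_out = sms_uc = calls_uc = avg_dur = 0.0
        missing.update(("sms_in", "sms_out", "sms_unique_contacts", "calls_in",
                        "calls_out", "calls_unique_contacts", "avg_call_duration_s"))

    # calendar
    if stream.calendar:
        evs = events_in(stream.calendar, lo, hi)
        cal = {s: 0.0 for s in ("morning", "afternoon", "evening")}
        for e in evs:
            cal[e.slot] += 1.0
    else:
        cal = {s: 0.0 for s in ("morning", "afternoon", "evening")}
        missing.update(("cal_morning", "cal_afternoon", "cal_evening"))

    return DayFeatures(
        day=day,
        general_activity=general, walking_min=min(walking, 1440.0),
        time_at_home_min=min(at_home, 1440.0), phone_use_min=min(phone_min, 1440.0),
        max_dist_m=max_d, total_dist_m=total_d, loc_var=loc_var,
        n_unique_wifi=n_unique,
        sms_in=sms_in, sms_out=sms_out, sms_unique_contacts=sms_uc,
        calls_in=calls_in, calls_out=calls_out, calls_unique_contacts=calls_uc,
        avg_call_duration_s=avg_dur,
        cal_morning=cal["morning"], cal_afternoon=cal["afternoon"],
        cal_evening=cal["evening"],
        n_gps_fixes=float(len(fixes)),
        missing=frozenset(missing),
    )


def subject_day_features(stream: SubjectStream,
                         config: FeatureConfig = FeatureConfig(),
                         home: HomeFingerprint | None = None) -> list[DayFeatures]:
    """Day-feature table over the subject's full local-date span.

    The home fingerprint is learned from the stream when not supplied.
    """
    if home is None:
        home = learn_home(stream.wifi, stream.tz_offset_hours, config)
    return [daily_base_features(stream, d, home, config) for d in stream.local_dates()]
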