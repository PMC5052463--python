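"""14-day window aggregation into the 120-dimensional feature vector.

Each biweekly questionnaire score is described by five statistics (mean,
sum, variance, minimum, maximum) of each of 24 base day-features over the
14 calendar days preceding the score.  The published work states the count
(24 x 5 = 120) but not the exact roster; the roster used here is the 18
directly-measured day features plus six documented derived totals, and is
the package's own documented convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .features import (
    BASE_DAY_FIELDS,
    DayFeatures,
    FeatureConfig,
    subject_day_features,
)
from .sensor_model import PHQ9_CUTOFF, Phq9Record, SubjectStream, local_date

#: Derived day-level totals appended to the 18 measured fields to form the
#: 24-feature base roster.
DERIVED_DAY_FIELDS = (
    "sms_total", "calls_total", "comm_unique_contacts_total",
    "cal_total", "dist_per_fix", "home_fraction",
)

BASE_FEATURES: tuple[str, ...] = BASE_DAY_FIELDS + DERIVED_DAY_FIELDS
STATS = ("mean", "sum", "variance", "min", "max")
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{base}__{stat}" for base in BASE_FEATURES for stat in STATS)

N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 120

WINDOW_DAYS = 14
DEFAULT_MIN_VALID_DAYS = 7
DEFAULT_MAX_MASKED_FEATURES = 4

#: Sources each derived field depends on; the derived value is masked on a
#: day where any source is masked.
_DERIVED_SOURCES = {
    "sms_total": ("sms_in", "sms_out"),
    "calls_total": ("calls_in", "calls_out"),
    "comm_unique_contacts_total": ("sms_unique_contacts", "calls_unique_contacts"),
    "cal_total": ("cal_morning", "cal_afternoon", "cal_evening"),
    "dist_per_fix": ("total_dist_m",),
    "home_fraction": ("time_at_home_min",),
}


class VectorDropped(ValueError):
    """Raised when too many base features lack enough valid days."""


@dataclass(frozen=True)
class FeatureVector:
    """120-value descriptor of the 14 days preceding one PHQ-9 record."""
    subject_id: str
    phq9_time: int
    values: np.ndarray                 # length 120, NaN where masked
    names: tuple[str, ...]
    label: bool                        # PHQ-9 >= 11
    score: int
    masked_bases: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.values) != N_FEATURES or self.names != FEATURE_NAMES:
            raise ValueError("feature vector must carry the canonical 120 names")


def day_feature_value(df: DayFeatures, name: str) -> tuple[float, bool]:
    """(value, is_masked) of a base feature — measured or derived — for one day."""
    if name in BASE_DAY_FIELDS:
        return df.value(name), df.is_missing(name)
    sources = _DERIVED_SOURCES[name]
    masked = any(df.is_missing(s) for s in sources)
    if name == "sms_total":
        v = df.sms_in + df.sms_out
    elif name == "calls_total":
        v = df.calls_in + df.calls_out
    elif name == "comm_unique_contacts_total":
        v = df.sms_unique_contacts + df.calls_unique_contacts
    elif name == "cal_total":
        v = df.cal_morning + df.cal_afternoon + df.cal_evening
    elif name == "dist_per_fix":
        if df.n_gps_fixes < 1:
            return 0.0, True
        v = df.total_dist_m / df.n_gps_fixes
    elif name == "home_fraction":
        v = df.time_at_home_min / 1440.0
    else:
        raise KeyError(name)
    return v, masked


def _stats(vals: np.ndarray) -> tuple[float, float, float, float, float]:
    return (float(np.mean(vals)), float(np.sum(vals)),
            float(np.var(vals)), float(np.min(vals)), float(np.max(vals)))


def feature_vector(day_features: Sequence[DayFeatures], phq9: Phq9Record,
                   subject_id: str = "",
                   min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
                   max_masked_features: int = DEFAULT_MAX_MASKED_FEATURES,
                   ) -> FeatureVector:
    """Aggregate exactly 14 consecutive day-feature rows into one vector.

    A base feature with fewer than ``min_valid_days`` unmasked days has its
    five statistics masked (NaN); the vector is dropped entirely when more
    than ``max_masked_features`` bases are masked.
    """
    if len(day_features) != WINDOW_DAYS:
        raise ValueError(f"need exactly {WINDOW_DAYS} day rows, got {len(day_features)}")
    for a, b in zip(day_features, day_features[1:]):
        if b.day != a.day + timedelta(days=1):
            raise ValueError("day rows must be consecutive calendar days in order")

    values = np.empty(N_FEATURES)
    masked_bases: list[str] = []
    for bi, base in enumerate(BASE_FEATURES):
        pairs = [day_feature_value(df, base) for df in day_features]
        vals = np.array([v for v, m in pairs if not m])
        if len(vals) < min_valid_days:
            values[bi * 5:(bi + 1) * 5] = np.nan
            masked_bases.append(base)
        else:
            values[bi * 5:(bi + 1) * 5] = _stats(vals)

    if len(masked_bases) > max_masked_features:
        raise VectorDropped(
            f"{len(masked_bases)} base features masked "
            f"(> {max_masked_features}): {masked_bases}")
    return FeatureVector(subject_id=subject_id, phq9_time=phq9.t, values=values,
                         names=FEATURE_NAMES, label=phq9.score >= PHQ9_CUTOFF,
                         score=phq9.score, masked_bases=tuple(masked_bases))


def subject_vectors(stream: SubjectStream,
                    config: FeatureConfig = FeatureConfig(),
                    min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
                    max_masked_features: int = DEFAULT_MAX_MASKED_FEATURES,
                    ) -> list[FeatureVector]:
    """One vector per PHQ-9 record preceded by >= 14 simulated days.

    The baseline record has no trailing window and never yields a vector, so
    a subject contributes iff it has post-baseline records (adherence of at
    least 2 weeks).
    """
    days = {df.day: df for df in subject_day_features(stream, config)}
    tz = stream.tz_offset_hours
    out: list[FeatureVector] = []
    for rec in stream.phq9:
        end = local_date(rec.t, tz)                       # window = 14 days before rec
        window = [days.get(end - timedelta(days=k)) for k in range(WINDOW_DAYS, 0, -1)]
        if any(w is None for w in window):
            continue
        try:
            out.append(feature_vector(window, rec, subject_id=stream.subject_id,
                                      min_valid_days=min_valid_days,
                                      max_masked_features=max_masked_features))
        except VectorDropped:
            continue
    return out


def day_features_frame(rows: Sequence[DayFeatures], subject_id: str = "") -> pd.DataFrame:
    """Tabular form of a day-feature list: values plus <field>__masked columns."""
    data = []
    for df in rows:
        rec: dict = {"subject_id": subject_id, "date": df.day.isoformat()}
        for name in BASE_DAY_FIELDS:
            rec[name] = df.value(name)
            rec[f"{name}__masked"] = int(df.is_missing(name))
        rec["n_gps_fixes"] = df.n_gps_fixes
        data.append(rec)
    return pd.DataFrame(data)


def build_dataset(streams: Sequence[SubjectStream],
                  config: FeatureConfig = FeatureConfig(),
                  min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
                  max_masked_features: int = DEFAULT_MAX_MASKED_FEATURES,
                  ) -> pd.DataFrame:
    """Cohort dataset: one row per (subject, post-baseline PHQ-9) pair."""
    records = []
    for stream in streams:
        for fv in subject_vectors(stream, config, min_valid_days, max_masked_features):
            rec = {"subject_id": fv.subject_id, "phq9_time": fv.phq9_time,
                   "score": fv.score, "label": int(fv.label)}
            rec.update(dict(zip(fv.names, fv.values)))
            records.append(rec)
    cols = ["subject_id", "phq9_time", "score", "label", *FEATURE_NAMES]
    return pd.DataFrame(records, columns=cols)
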