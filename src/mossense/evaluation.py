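"""Trial-style statistics: session counting, adherence bands, symptom
progression tests and the usage-change correlation.

Wilcoxon signed-rank convention: zero differences are dropped (Wilcoxon's
original treatment), the exact null distribution is used for n <= 25 when
the absolute differences are tie-free, and the normal approximation with
tie correction otherwise.  All p-values are two-sided.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .sensor_model import MS_PER_DAY, AppSession, SubjectStream

WEEK_MS = 7 * MS_PER_DAY
EPOCH_WEEKS = 2
MIN_TEST_N = 5


class CohortError(ValueError):
    pass


@dataclass
class SubjectRecord:
    subject_id: str
    enrollment: int
    last_activity: int
    phq9_series: list[tuple[int, int]]   # time-ordered (t, score)
    n_sessions: int = 0                  # qualifying app uses

    @property
    def adherence_weeks(self) -> float:
        return max(0.0, (self.last_activity - self.enrollment) / WEEK_MS)

    @property
    def baseline_phq9(self) -> int | None:
        return self.phq9_series[0][1] if self.phq9_series else None

    @property
    def n_post_baseline(self) -> int:
        return max(0, len(self.phq9_series) - 1)


@dataclass
class CohortTable:
    subjects: list[SubjectRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.subjects)

    @classmethod
    def from_streams(cls, streams: Sequence[SubjectStream]) -> "CohortTable":
        rows = []
        for s in streams:
            events = [ev.t for kind in s._kinds().values() for ev in kind]
            last = max(events, default=s.enrollment)
            rows.append(SubjectRecord(
                subject_id=s.subject_id, enrollment=s.enrollment, last_activity=last,
                phq9_series=[(r.t, r.score) for r in s.phq9],
                n_sessions=count_sessions(s.sessions)))
        return cls(rows)


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float       # z for Wilcoxon, rho for Spearman
    p_value: float
    n: int
    degenerate: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.degenerate and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def count_sessions(sessions: Sequence[AppSession]) -> int:
    """App uses: sessions with at least one intervention execution."""
    return sum(1 for s in sessions if s.interventions_executed >= 1)


# ---------------------------------------------------------------------------
# adherence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdherenceSummary:
    n: int
    counts: dict                 # band -> count
    percents: dict               # band -> percent, one decimal

    BANDS = ("lt_2wk", "wk_2_4", "ge_4wk", "other")


def adherence_summary(cohort: CohortTable) -> AdherenceSummary:
    """Attrition bands: < 2 weeks, 2-4 weeks, and >= 4 weeks with at least 2
    post-baseline questionnaire scores; subjects at >= 4 weeks without the
    required scores fall into ``other``.  Percentages are rounded to one
    decimal."""
    if not cohort.subjects:
        raise CohortError("empty cohort")
    counts = dict.fromkeys(AdherenceSummary.BANDS, 0)
    for s in cohort.subjects:
        w = s.adherence_weeks
        if w < 2:
            counts["lt_2wk"] += 1
        elif w < 4:
            counts["wk_2_4"] += 1
        elif s.n_post_baseline >= 2:
            counts["ge_4wk"] += 1
        else:
            counts["other"] += 1
    n = len(cohort.subjects)
    percents = {b: round(100.0 * c / n, 1) for b, c in counts.items()}
    return AdherenceSummary(n=n, counts=counts, percents=percents)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Reports the tie-corrected normal z statistic; the p-value comes from the
    exact null when n <= 25 with untied absolute differences, otherwise from
    the normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    d = y - x
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return TestResult("wilcoxon", 0.0, 1.0, 0, degenerate=True)

    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = 0.0 if sigma2 <= 0 else (w_plus - mu) / math.sqrt(sigma2)

    no_ties = len(np.unique(np.abs(d))) == n
    if n <= 25 and no_ties:
        method = "exact"
        res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                             method="exact")
        p = float(res.pvalue)
    else:
        method = "approx"
        p = 2.0 * stats.norm.sf(abs(z)) if sigma2 > 0 else 1.0
        p = min(1.0, p)
    return TestResult("wilcoxon", z, p, n, extras={"w_plus": w_plus, "method": method})


# ---------------------------------------------------------------------------
# symptom progression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProgressionResult:
    horizon_weeks: int
    n: int
    z: float
    p_value: float
    median_t0: float
    iqr_t0: tuple[float, float]
    median_tn: float
    iqr_tn: tuple[float, float]
    ks_statistic: float
    ks_p: float
    degenerate: bool = False


def _iqr(v: np.ndarray) -> tuple[float, float]:
    return (float(np.percentile(v, 25)), float(np.percentile(v, 75)))


def phq9_progression_test(cohort: CohortTable, baseline_min: int = 11,
                          min_adherence_weeks: float = 4.0,
                          min_post_baseline: int = 2,
                          min_n: int = MIN_TEST_N) -> list[ProgressionResult]:
    """Paired signed-rank tests of the biweekly scores against baseline.

    Eligible subjects are clinically flagged at baseline (score >=
    ``baseline_min``), adhered at least ``min_adherence_weeks`` weeks and
    provided at least ``min_post_baseline`` post-baseline scores.  t_0 is each
    subject's first record; horizon k compares record k against t_0 for
    subjects with a record at k.  A Kolmogorov-Smirnov normality check on the
    paired differences is recorded alongside each test.
    """
    eligible = [s for s in cohort.subjects
                if s.baseline_phq9 is not None and s.baseline_phq9 >= baseline_min
                and s.adherence_weeks >= min_adherence_weeks
                and s.n_post_baseline >= min_post_baseline]
    if not eligible:
        return []
    max_h = max(s.n_post_baseline for s in eligible)
    out: list[ProgressionResult] = []
    for k in range(1, max_h + 1):
        pairs = [(s.phq9_series[0][1], s.phq9_series[k][1])
                 for s in eligible if len(s.phq9_series) > k]
        if len(pairs) < min_n:
            continue
        t0 = np.array([a for a, _ in pairs], dtype=float)
        tn = np.array([b for _, b in pairs], dtype=float)
        res = wilcoxon_signed_rank(t0, tn)
        diffs = tn - t0
        if np.std(diffs) > 0:
            ks = stats.kstest((diffs - diffs.mean()) / diffs.std(), "norm")
            ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
        else:
            ks_stat, ks_p = 0.0, 1.0
        out.append(ProgressionResult(
            horizon_weeks=EPOCH_WEEKS * k, n=len(pairs),
            z=res.statistic, p_value=res.p_value,
            median_t0=float(np.median(t0)), iqr_t0=_iqr(t0),
            median_tn=float(np.median(tn)), iqr_tn=_iqr(tn),
            ks_statistic=ks_stat, ks_p=ks_p, degenerate=res.degenerate))
    return out


# ---------------------------------------------------------------------------
# usage-change correlation
# ---------------------------------------------------------------------------

def usage_symptom_correlation(cohort: CohortTable, baseline_min: int = 11,
                              min_adherence_weeks: float = 4.0,
                              min_post_baseline: int = 2,
                              min_n: int = MIN_TEST_N) -> TestResult:
    """Spearman correlation of total qualifying sessions with the change in
    score between t_0 and each subject's last record (t_end - t_0)."""
    eligible = [s for s in cohort.subjects
                if s.baseline_phq9 is not None and s.baseline_phq9 >= baseline_min
                and s.adherence_weeks >= min_adherence_weeks
                and s.n_post_baseline >= min_post_baseline]
    if len(eligible) < min_n:
        raise CohortError(f"need >= {min_n} eligible subjects, have {len(eligible)}")
    usage = np.array([s.n_sessions for s in eligible], dtype=float)
    change = np.array([s.phq9_series[-1][1] - s.phq9_series[0][1] for s in eligible],
                      dtype=float)
    if np.all(usage == usage[0]) or np.all(change == change[0]):
        return TestResult("spearman", float("nan"), 1.0, len(eligible),
                          degenerate=True)
    rho, p = stats.spearmanr(usage, change)
    return TestResult("spearman", float(rho), float(p), len(eligible))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_COHORT_COLUMNS = ["subject_id", "enrollment_ms", "last_activity_ms",
                   "phq9_series", "n_sessions"]


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COHORT_COLUMNS)
        for s in cohort.subjects:
            series = ";".join(f"{t}:{v}" for t, v in s.phq9_series)
            writer.writerow([s.subject_id, s.enrollment, s.last_activity,
                             series, s.n_sessions])


def read_cohort_csv(path: str | Path) -> CohortTable:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_COHORT_COLUMNS) <= set(reader.fieldnames):
            raise CohortError(f"cohort CSV must have columns {_COHORT_COLUMNS}")
        for row in reader:
            series = [(int(p.split(":")[0]), int(p.split(":")[1]))
                      for p in row["phq9_series"].split(";") if p]
            rows.append(SubjectRecord(
                subject_id=row["subject_id"], enrollment=int(row["enrollment_ms"]),
                last_activity=int(row["last_activity_ms"]),
                phq9_series=series, n_sessions=int(row["n_sessions"])))
    return CohortTable(rows)


def evaluation_report(cohort: CohortTable, baseline_min: int = 11,
                      min_adherence_weeks: float = 4.0) -> dict:
    """Adherence bands, per-horizon progression tests and the usage
    correlation, in one JSON-ready document."""
    summary = adherence_summary(cohort)
    progression = phq9_progression_test(cohort, baseline_min, min_adherence_weeks)
    try:
        corr = usage_symptom_correlation(cohort, baseline_min, min_adherence_weeks)
        corr_doc = asdict(corr)
    except CohortError as exc:
        corr_doc = {"error": str(exc)}
    return {
        "n_subjects": summary.n,
        "adherence": {"counts": summary.counts, "percents": summary.percents},
        "progression": [asdict(p) for p in progression],
        "usage_correlation": corr_doc,
    }
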